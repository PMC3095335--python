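"""Distance-based phylogenetics: p-distances, neighbor joining, bootstrap, clock dating.

Trees are ``dendropy.Tree`` objects throughout the package; bootstrap supports
are stored as internal-node labels (integer percentages), matching the common
Newick convention. Neighbor joining is the Saitou-Nei agglomeration with the
Q-criterion; on additive distance matrices it reproduces the generating tree's
path lengths exactly. Negative branch-length estimates are clamped to zero.

A simplified strict molecular clock converts a pairwise distance into an age
via a single calibration split: rate r = d_cal / (2 t_cal), age = d / (2 r).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np

from .seqio import GAP, CodonAlignment, ProteinAlignment

logger = logging.getLogger(__name__)

PDistanceMode = str  # {"protein", "nucleotide", "nucleotide_transversion"}

_PURINES = [b"A", b"G"]


@dataclass
class DistanceMatrix:
    """Symmetric distance matrix with NaN marking undefined (incomparable) pairs."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("distance matrix is not symmetric")
        self.values = v

    def get(self, id_a: str, id_b: str) -> float:
        return float(self.values[self.ids.index(id_a), self.ids.index(id_b)])

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                if math.isnan(self.values[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out


def _as_char_matrix(aln: ProteinAlignment | CodonAlignment) -> np.ndarray:
    rows = [r.seq for r in aln.records]
    return np.frombuffer("".join(rows).encode(), dtype="S1").reshape(len(rows), -1)


def p_distance(
    aln: ProteinAlignment | CodonAlignment,
    mode: PDistanceMode = "protein",
    deletion: str = "pairwise",
) -> DistanceMatrix:
    """Proportion of differing compared positions for every sequence pair.

    ``nucleotide_transversion`` counts only purine<->pyrimidine differences in
    the numerator (the denominator stays all compared positions). ``pairwise``
    deletion drops positions gapped in either member of a pair; ``complete``
    drops positions gapped in any sequence before any comparison.
    """
    if mode not in ("protein", "nucleotide", "nucleotide_transversion"):
        raise ValueError(f"unknown p-distance mode {mode!r}")
    if deletion not in ("pairwise", "complete"):
        raise ValueError(f"unknown deletion policy {deletion!r}")
    mat = _as_char_matrix(aln)
    missing = (mat == GAP.encode()) | (mat == b"N") | (mat == b"X")
    if deletion == "complete":
        keep = ~missing.any(axis=0)
        mat, missing = mat[:, keep], missing[:, keep]
    n = mat.shape[0]
    is_purine = np.isin(mat, _PURINES)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~missing[i] & ~missing[j]
            compared = int(ok.sum())
            if compared == 0:
                D[i, j] = D[j, i] = math.nan
                continue
            diff = mat[i, ok] != mat[j, ok]
            if mode == "nucleotide_transversion":
                diff &= is_purine[i, ok] != is_purine[j, ok]
            D[i, j] = D[j, i] = diff.sum() / compared
    return DistanceMatrix(list(aln.ids), D)


def neighbor_joining(D: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; exact on additive matrices.

    Ties in the Q-criterion are broken by the lexicographically smallest
    active index pair; negative branch-length estimates are clamped to 0.
    """
    bad = D.undefined_pairs()
    if bad:
        raise ValueError(f"distance matrix has undefined pairs: {bad}")
    n0 = len(D.ids)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")

    def fmt(x: float) -> str:
        return f"{max(x, 0.0):.10g}"

    active = list(range(n0))  # indices into growing distance store
    dist = {(i, j): float(D.values[i, j]) for i in range(n0) for j in range(n0) if i < j}
    label = {i: _quote_newick_label(D.ids[i]) for i in range(n0)}
    next_idx = n0

    def d(i: int, j: int) -> float:
        return 0.0 if i == j else dist[(min(i, j), max(i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d(i, k) for k in active) for i in active}
        best, best_q = None, math.inf
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d(i, j) - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q, best = q, (i, j)
        i, j = best
        li = d(i, j) / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = d(i, j) - li
        if li < 0 or lj < 0:
            logger.info("clamping negative NJ branch length to 0 at join (%s,%s)", i, j)
        label[next_idx] = f"({label[i]}:{fmt(li)},{label[j]}:{fmt(lj)})"
        for k in active:
            if k in (i, j):
                continue
            dist[(min(k, next_idx), max(k, next_idx))] = max(
                (d(i, k) + d(j, k) - d(i, j)) / 2, 0.0
            )
        active = [k for k in active if k not in (i, j)] + [next_idx]
        next_idx += 1

    a, b, c = active
    la = (d(a, b) + d(a, c) - d(b, c)) / 2
    lb = (d(a, b) + d(b, c) - d(a, c)) / 2
    lc = (d(a, c) + d(b, c) - d(a, b)) / 2
    newick = f"({label[a]}:{fmt(la)},{label[b]}:{fmt(lb)},{label[c]}:{fmt(lc)});"
    return dendropy.Tree.get(data=newick, schema="newick")


def _quote_newick_label(lab: str) -> str:
    if any(ch in lab for ch in "():;, '\t\n[]"):
        return "'" + lab.replace("'", "''") + "'"
    return lab


def leaf_bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial splits of the leaf set, one canonical side per internal edge."""
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(leaves)
    splits: set[frozenset[str]] = set()
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if len(below) < 2 or len(leaves - below) < 2:
            continue
        side = below if ref not in below else leaves - below
        splits.add(frozenset(side))
    return splits


def _resample_alignment(
    aln: ProteinAlignment | CodonAlignment, cols: np.ndarray
) -> ProteinAlignment | CodonAlignment:
    from .seqio import SequenceRecord

    if isinstance(aln, CodonAlignment):
        rows = [
            SequenceRecord(r.id, "".join(r.seq[3 * c : 3 * c + 3] for c in cols))
            for r in aln.records
        ]
        return CodonAlignment(rows, aln.genetic_code)
    rows = [SequenceRecord(r.id, "".join(r.seq[c] for c in cols)) for r in aln.records]
    return ProteinAlignment(rows)


def bootstrap_support(
    aln: ProteinAlignment | CodonAlignment,
    mode: PDistanceMode = "protein",
    deletion: str = "pairwise",
    n_reps: int = 1000,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with bootstrap supports on internal edges.

    Columns (codon columns for codon alignments) are resampled with
    replacement; support is the percentage of replicates whose NJ tree
    contains each internal bipartition of the point-estimate tree.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n_cols = aln.n_codon_cols if isinstance(aln, CodonAlignment) else aln.n_cols
    if n_cols < 2:
        raise ValueError("alignment too short to bootstrap")
    tree = neighbor_joining(p_distance(aln, mode, deletion))
    target = leaf_bipartitions(tree)
    counts = {split: 0 for split in target}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        cols = np.sort(rng.integers(0, n_cols, size=n_cols))
        rep_tree = neighbor_joining(p_distance(_resample_alignment(aln, cols), mode, deletion))
        for split in leaf_bipartitions(rep_tree):
            if split in counts:
                counts[split] += 1
    leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    ref = min(leaves)
    for node in tree.postorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        below = {lf.taxon.label for lf in node.leaf_iter()}
        if len(below) < 2 or len(leaves - below) < 2:
            continue
        side = frozenset(below if ref not in below else leaves - below)
        node.label = str(round(100 * counts[side] / n_reps))
    return tree


@dataclass(frozen=True)
class ClockCalibration:
    """A calibration split: distance ``d_cal`` spans an event of age ``t_cal`` Mya."""

    d_cal: float
    t_cal: float

    def __post_init__(self) -> None:
        if self.d_cal <= 0 or self.t_cal <= 0:
            raise ValueError("calibration distance and age must be positive")


def strict_clock_age(d_pair: float, cal: ClockCalibration) -> float:
    """Age (Mya) of the split behind ``d_pair`` under a global strict clock."""
    if d_pair < 0:
        raise ValueError("distance must be non-negative")
    return cal.t_cal * d_pair / cal.d_cal


def read_newick(source: str | Path) -> dendropy.Tree:
    """Parse a Newick tree (path or literal string); internal labels kept as supports."""
    text = str(source)
    if not text.lstrip().startswith("(") and Path(text).exists():
        text = Path(text).read_text()
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    dups = {l for l in labels if labels.count(l) > 1}
    if dups:
        raise ValueError(f"duplicate leaf labels in tree: {sorted(dups)}")
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    text = tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".6f",
    )
    Path(path).write_text(text)


def tree_path_distance(tree: dendropy.Tree, label_a: str, label_b: str) -> float:
    """Sum of branch lengths on the path between two leaves."""
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    return float(pdm.distance(tax[label_a], tax[label_b]))
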