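"""Seeded simulators for every analysis stage.

These generate data with exactly the statistical structure the estimators
assume: codon alignments evolved under site-class omega mixtures on a fixed
tree (optionally with branch-specific omega), gamma-Poisson change counts
with a rate-decoupled site fraction (the Type-I generating model), grouped
protein alignments with planted specificity-determining columns, and paralog
codon pairs whose fourfold-degenerate third positions diverge under a
Kimura-style process (or are fully saturated). Every simulator is a pure
function of its parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy import linalg

from ._gencode import FOURFOLD_PREFIXES, SENSE_CODONS
from .codon_models import CodonModel, codon_rate_matrix
from .func_divergence import ChangeCountTable
from .seqio import CodonAlignment, GroupAssignment, ProteinAlignment, SequenceRecord

_NT = "TCAG"


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated dataset."""

    seed: int
    params: dict
    site_labels: np.ndarray = field(default_factory=lambda: np.array([]))


def _draw_rows(P: np.ndarray, parents: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Child states from parent states under row-stochastic P (inverse CDF)."""
    cum = np.cumsum(P, axis=1)
    cum[:, -1] = 1.0
    rows = cum[parents]
    return (rows < u[:, None]).sum(axis=1)


def simulate_codon_alignment(
    tree: dendropy.Tree,
    model: CodonModel,
    n_codons: int,
    seed: int = 0,
    branch_omegas: dict[str, float] | None = None,
) -> tuple[CodonAlignment, SimulationTruth]:
    """Evolve a codon alignment down ``tree`` under a site-class omega mixture.

    Each site draws its omega class from the model's proportions; the root
    codon is drawn from the stationary frequencies and propagated along each
    branch with P(t) = expm(Q t). ``branch_omegas`` (keyed by child taxon
    label or internal node label) overrides the site-class omega on specific
    branches, for branch-model simulations.
    """
    rng = np.random.default_rng(seed)
    pi = model.codon_freqs
    props, omegas = model.proportions, model.omegas
    classes = rng.choice(len(props), size=n_codons, p=props)

    _P_cache: dict[tuple[float, float], np.ndarray] = {}

    def P_for(omega: float, t: float) -> np.ndarray:
        key = (omega, t)
        if key not in _P_cache:
            Q = codon_rate_matrix(model.kappa, omega, pi)
            _P_cache[key] = np.maximum(linalg.expm(Q * t), 0.0)
        return _P_cache[key]

    states = {id(tree.seed_node): rng.choice(61, size=n_codons, p=pi / pi.sum())}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        t = float(node.edge.length or 0.0)
        label = (
            node.taxon.label
            if node.is_leaf()
            else (node.label or "")
        )
        override = branch_omegas.get(label) if branch_omegas else None
        parent = states[id(node.parent_node)]
        child = np.empty(n_codons, dtype=np.int64)
        u = rng.random(n_codons)
        for k, w in enumerate(omegas):
            mask = classes == k
            if not mask.any():
                continue
            P = P_for(override if override is not None else w, t)
            child[mask] = _draw_rows(P, parent[mask], u[mask])
        states[id(node)] = child

    records = [
        SequenceRecord(
            lf.taxon.label, "".join(SENSE_CODONS[s] for s in states[id(lf)])
        )
        for lf in tree.leaf_node_iter()
    ]
    truth = SimulationTruth(
        seed=seed,
        params={
            "kappa": model.kappa,
            "omega_classes": model.omega_classes,
            "n_codons": n_codons,
            "branch_omegas": branch_omegas,
        },
        site_labels=classes,
    )
    return CodonAlignment(records), truth


def simulate_rate_shift_counts(
    n_sites: int,
    theta: float,
    alpha: float,
    d1: float,
    d2: float,
    seed: int = 0,
    labels: tuple[str, str] = ("cluster1", "cluster2"),
) -> tuple[ChangeCountTable, SimulationTruth]:
    """Per-site change counts under the Type-I generating model.

    With probability theta a site draws independent gamma(alpha, alpha) rates
    in the two clusters, otherwise one shared rate; counts are
    Poisson(rate * d_c).
    """
    if not 0 <= theta <= 1:
        raise ValueError("theta must be in [0, 1]")
    if alpha <= 0 or d1 <= 0 or d2 <= 0:
        raise ValueError("alpha, d1, d2 must be positive")
    rng = np.random.default_rng(seed)
    shifted = rng.random(n_sites) < theta
    lam_shared = rng.gamma(alpha, 1.0 / alpha, size=n_sites)
    lam1 = np.where(shifted, rng.gamma(alpha, 1.0 / alpha, size=n_sites), lam_shared)
    lam2 = np.where(shifted, rng.gamma(alpha, 1.0 / alpha, size=n_sites), lam_shared)
    x1 = rng.poisson(lam1 * d1)
    x2 = rng.poisson(lam2 * d2)
    truth = SimulationTruth(
        seed=seed,
        params={"theta": theta, "alpha": alpha, "d1": d1, "d2": d2},
        site_labels=shifted.astype(int),
    )
    return ChangeCountTable(np.stack([x1, x2], axis=1), labels), truth


def simulate_grouped_alignment(
    n_per_group: Sequence[int],
    n_cols: int,
    sdp_spec: list[tuple[int, Sequence[str]]],
    background_profile: np.ndarray | None = None,
    error_rate: float = 0.05,
    seed: int = 0,
    group_labels: Sequence[str] | None = None,
) -> tuple[ProteinAlignment, GroupAssignment, SimulationTruth]:
    """Protein alignment with planted group-specific (SDP) columns.

    ``sdp_spec`` lists (column, residue-per-group); planted columns draw each
    group's assigned residue with probability 1 - error_rate (otherwise a
    random residue); background columns are i.i.d. from one shared profile in
    every group, so they carry no group signal.
    """
    aa = "ACDEFGHIKLMNPQRSTVWY"
    n_groups = len(n_per_group)
    cols_seen = set()
    for col, residues in sdp_spec:
        if not 0 <= col < n_cols:
            raise ValueError(f"planted column {col} outside 0..{n_cols - 1}")
        if col in cols_seen:
            raise ValueError(f"column {col} planted twice")
        cols_seen.add(col)
        if len(residues) != n_groups:
            raise ValueError(f"column {col}: need one residue per group")
    rng = np.random.default_rng(seed)
    if background_profile is None:
        background_profile = np.full(20, 0.05)
    background_profile = np.asarray(background_profile, float)
    background_profile = background_profile / background_profile.sum()
    labels = list(group_labels) if group_labels else [f"group{g + 1}" for g in range(n_groups)]

    planted = {col: residues for col, residues in sdp_spec}
    rows, assignment = [], GroupAssignment()
    idx = 0
    for g, n in enumerate(n_per_group):
        for _ in range(n):
            seq = list(aa[i] for i in rng.choice(20, size=n_cols, p=background_profile))
            for col, residues in planted.items():
                if rng.random() < error_rate:
                    seq[col] = aa[rng.integers(20)]
                else:
                    seq[col] = residues[g]
            name = f"{labels[g]}_s{idx}"
            rows.append(SequenceRecord(name, "".join(seq)))
            assignment[name] = labels[g]
            idx += 1
    site_labels = np.zeros(n_cols, dtype=int)
    site_labels[list(planted)] = 1
    truth = SimulationTruth(
        seed=seed,
        params={"n_per_group": list(n_per_group), "error_rate": error_rate,
                "planted_columns": sorted(planted)},
        site_labels=site_labels,
    )
    return ProteinAlignment(rows), assignment, truth


def _k2p_matrix(t: float, kappa: float) -> np.ndarray:
    """4x4 Kimura transition matrix over TCAG at divergence t."""
    Q = np.zeros((4, 4))
    for i, a in enumerate(_NT):
        for j, b in enumerate(_NT):
            if i == j:
                continue
            ts = (a in "AG") == (b in "AG")
            Q[i, j] = kappa if ts else 1.0
    Q[np.diag_indices(4)] = -Q.sum(axis=1)
    Q /= kappa + 2.0  # uniform base freqs: mean rate = kappa + 2
    return np.maximum(linalg.expm(Q * t), 0.0)


def simulate_paralog_pair(
    n_codons: int,
    third_pos_branch_length: float | None = None,
    kappa: float = 2.0,
    seed: int = 0,
    saturation: bool = False,
    ids: tuple[str, str] = ("paralog1", "paralog2"),
) -> CodonAlignment:
    """A codon-aligned paralog pair diverged only at fourfold third positions.

    Every codon sits in a fourfold-degenerate box, so all columns are
    conserved 4D sites. In ``saturation`` mode both third positions are drawn
    i.i.d. uniform over the four nucleotides (the ancient-divergence limit,
    expected 4DTv = 0.5); otherwise the second sequence's third positions
    evolve from the first under a Kimura two-parameter process at the given
    branch length.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be positive")
    rng = np.random.default_rng(seed)
    prefixes = sorted(FOURFOLD_PREFIXES)
    pre = rng.choice(len(prefixes), size=n_codons)
    third1 = rng.integers(0, 4, size=n_codons)
    if saturation:
        third2 = rng.integers(0, 4, size=n_codons)
    else:
        if third_pos_branch_length is None or third_pos_branch_length < 0:
            raise ValueError("third_pos_branch_length must be >= 0")
        P = _k2p_matrix(third_pos_branch_length, kappa)
        third2 = _draw_rows(P, third1, rng.random(n_codons))
    seq1 = "".join(prefixes[p] + _NT[t] for p, t in zip(pre, third1))
    seq2 = "".join(prefixes[p] + _NT[t] for p, t in zip(pre, third2))
    return CodonAlignment(
        [SequenceRecord(ids[0], seq1), SequenceRecord(ids[1], seq2)]
    )


def balanced_tree(n_taxa: int, branch_length: float = 0.2, prefix: str = "t") -> dendropy.Tree:
    """A balanced (caterpillar-free) topology with equal branch lengths.

    Handy default topology for simulation studies; taxa are ``t1..tN``.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    items = [f"{prefix}{i + 1}:{branch_length}" for i in range(n_taxa)]
    while len(items) > 2:
        nxt = []
        for k in range(0, len(items) - 1, 2):
            nxt.append(f"({items[k]},{items[k + 1]}):{branch_length}")
        if len(items) % 2:
            nxt.append(items[-1])
        items = nxt
    newick = f"({items[0]},{items[1]});"
    return dendropy.Tree.get(data=newick, schema="newick")
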