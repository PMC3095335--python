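"""Specificity-determining positions (SDPs) by mutual information.

An SDP is an alignment column whose residue composition tracks the functional
subgroup of the sequences (e.g. monocot vs dicot orthologs). Each column is
scored by the mutual information (in bits, by default) between residue
identity and group label,

    I = sum_{a,g} f(a,g) log2[ f(a,g) / (f(a) f(g)) ],

with additive smoothing f(a|g) = (n(a,g) + lambda q_a) / (N_g + lambda)
toward the overall residue frequencies q_a. Raw MI is biased upward in small
columns, so significance comes from a permutation null: group labels are
shuffled across sequences (one permutation per replicate, applied to every
column) and each column's Z-score is its MI standardized by the shuffle mean
and standard deviation. A recognition cutoff on the ranked Z-scores is chosen
by a Bernoulli (binomial-tail) estimator: for each candidate count L, B(L) is
the log10 probability that at least L of the N scored columns would exceed
the L-th ranked score by chance; the L minimizing B(L) is the cutoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .seqio import GAP, GroupAssignment, ProteinAlignment

_AA = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {a: i for i, a in enumerate(_AA)}


@dataclass
class SDPResult:
    """Per-column MI and Z-scores, the B(L) curve, and the selected SDP set."""

    mi: np.ndarray  # NaN for columns not scored (gap-heavy)
    z: np.ndarray  # NaN for columns not scored
    scored_columns: list[int]
    ranked_columns: list[int]  # scored columns by descending Z
    b_curve: np.ndarray  # B(L) for L = 1..n_scored
    cutoff_l: int
    sdps: list[int]  # selected columns, descending Z
    group_residues: dict[int, dict[str, str]]  # column -> {group: consensus residue}


def _column_counts(
    aln: ProteinAlignment, groups: GroupAssignment, column: int
) -> tuple[np.ndarray, int]:
    """Residue count matrix (n_groups, 20) at a column and the gap count."""
    labels = groups.labels()
    counts = np.zeros((len(labels), 20))
    gaps = 0
    for rec in aln.records:
        ch = rec.seq[column]
        if ch in (GAP, "X"):
            gaps += 1
            continue
        counts[labels.index(groups[rec.id]), _AA_INDEX[ch]] += 1
    return counts, gaps


def _overall_freqs(aln: ProteinAlignment) -> np.ndarray:
    q = np.zeros(20)
    for rec in aln.records:
        for ch in rec.seq:
            if ch in _AA_INDEX:
                q[_AA_INDEX[ch]] += 1
    return q / q.sum() if q.sum() else np.full(20, 0.05)


def _mi_from_counts(counts: np.ndarray, q: np.ndarray, pseudocount: float) -> float:
    n_g = counts.sum(axis=1)
    present = n_g > 0
    counts, n_g = counts[present], n_g[present]
    f_cond = (counts + pseudocount * q[None, :]) / (n_g + pseudocount)[:, None]
    f_g = n_g / n_g.sum()
    joint = f_cond * f_g[:, None]
    f_a = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log2(joint / (f_a[None, :] * f_g[:, None]))
    return float(np.nansum(term))


def column_mi(
    aln: ProteinAlignment,
    groups: GroupAssignment,
    column: int,
    pseudocount: float = 1.0,
    max_gap_fraction: float = 0.1,
) -> float:
    """Mutual information (bits) between residue and group at one column.

    Columns with more than ``max_gap_fraction`` gapped rows are not scored
    (NaN). With ``pseudocount = 0`` this is the plug-in MI, bounded by
    log2(number of groups).
    """
    if not 0 <= column < aln.n_cols:
        raise IndexError(f"column {column} out of range (0..{aln.n_cols - 1})")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    groups.validate_against(aln.ids)
    counts, gaps = _column_counts(aln, groups, column)
    if gaps > max_gap_fraction * aln.n_seqs:
        return math.nan
    return _mi_from_counts(counts, _overall_freqs(aln), pseudocount)


def bernoulli_cutoff(
    z_sorted: np.ndarray, tail: str = "normal", z_pool: np.ndarray | None = None
) -> tuple[int, np.ndarray]:
    """Select how many top-ranked columns to call, by binomial tail probability.

    For each L, eps_L = P(Z >= z_(L)) under the null (standard normal, or the
    empirical pool of shuffle Z-scores) and B(L) = log10 P(Binomial(N, eps_L)
    >= L). Returns (argmin_L B(L), the full curve); numerical ties go to the
    smallest L.
    """
    z = np.asarray(z_sorted, dtype=float)
    if z.size == 0:
        raise ValueError("no scores to threshold")
    if np.any(np.diff(z) > 1e-12):
        raise ValueError("z_sorted must be in descending order")
    n = z.size
    if tail == "normal":
        eps = stats.norm.sf(z)
    elif tail == "empirical":
        if z_pool is None or len(z_pool) == 0:
            raise ValueError("empirical tail needs a pool of null Z-scores")
        pool = np.sort(np.asarray(z_pool, dtype=float))
        eps = 1.0 - np.searchsorted(pool, z, side="left") / pool.size
        eps = np.maximum(eps, 1.0 / (pool.size + 1))
    else:
        raise ValueError(f"unknown tail estimator {tail!r}")
    L = np.arange(1, n + 1)
    with np.errstate(divide="ignore"):
        b = np.log10(np.maximum(stats.binom.sf(L - 1, n, eps), 1e-300))
    best = float(np.min(b))
    cutoff = int(L[np.isclose(b, best, rtol=1e-9, atol=1e-12)][0])
    return cutoff, b


def sdp_scan(
    aln: ProteinAlignment,
    groups: GroupAssignment,
    n_shuffles: int = 1000,
    pseudocount: float = 1.0,
    seed: int = 0,
    max_gap_fraction: float = 0.1,
    tail: str = "normal",
) -> SDPResult:
    """Scan every column for group-specific composition.

    Group labels are permuted across sequences ``n_shuffles`` times (the same
    permutation for all columns within a replicate); each scored column's
    Z-score is (MI - shuffle mean) / shuffle sd (0 where sd = 0). Columns are
    ranked by Z and the Bernoulli estimator picks the cutoff; columns with
    Z <= 0 are never reported as SDPs. Deterministic for a given seed.
    """
    groups.validate_against(aln.ids)
    labels = groups.labels()
    small = [lab for lab in labels if len(groups.members(lab)) < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 sequences: {small}")

    n_seqs, n_cols = aln.n_seqs, aln.n_cols
    q = _overall_freqs(aln)
    group_idx = np.array([labels.index(groups[rec.id]) for rec in aln.records])

    # residue index matrix, -1 for gaps
    res = np.full((n_seqs, n_cols), -1, dtype=np.int64)
    for i, rec in enumerate(aln.records):
        for j, ch in enumerate(rec.seq):
            res[i, j] = _AA_INDEX.get(ch, -1)
    gap_frac = (res < 0).sum(axis=0) / n_seqs
    scored = [j for j in range(n_cols) if gap_frac[j] <= max_gap_fraction]

    onehot = np.zeros((n_seqs, n_cols, 20))
    ok = res >= 0
    onehot[np.where(ok)[0], np.where(ok)[1], res[ok]] = 1.0

    def mi_all(gidx: np.ndarray) -> np.ndarray:
        member = np.stack([(gidx == g).astype(float) for g in range(len(labels))])
        counts = np.einsum("gs,sca->gca", member, onehot)  # (groups, cols, 20)
        return np.array(
            [_mi_from_counts(counts[:, j], q, pseudocount) for j in scored]
        )

    mi_obs = mi_all(group_idx)
    rng = np.random.default_rng(seed)
    # canonicalize shuffles over id-sorted sequences so Z-scores do not
    # depend on the order records appear in the alignment
    sorted_pos = np.argsort(np.argsort(aln.ids))  # record -> rank of its id
    labels_by_rank = np.empty(n_seqs, dtype=np.int64)
    labels_by_rank[sorted_pos] = group_idx
    null = np.empty((n_shuffles, len(scored)))
    for r in range(n_shuffles):
        shuffled_by_rank = labels_by_rank[rng.permutation(n_seqs)]
        null[r] = mi_all(shuffled_by_rank[sorted_pos])
    mean, sd = null.mean(axis=0), null.std(axis=0, ddof=1)
    z_scored = np.where(sd > 0, (mi_obs - mean) / np.where(sd > 0, sd, 1.0), 0.0)

    mi = np.full(n_cols, math.nan)
    z = np.full(n_cols, math.nan)
    for k, j in enumerate(scored):
        mi[j], z[j] = mi_obs[k], z_scored[k]

    order = sorted(range(len(scored)), key=lambda k: (-z_scored[k], scored[k]))
    ranked = [scored[k] for k in order]
    z_pool = null_z_pool(null) if tail == "empirical" else None
    cutoff_l, b_curve = bernoulli_cutoff(z_scored[order], tail=tail, z_pool=z_pool)
    sdps = [c for c in ranked[:cutoff_l] if z[c] > 0]

    group_residues = {}
    for c in sdps:
        counts, _ = _column_counts(aln, groups, c)
        group_residues[c] = {
            lab: _AA[int(np.argmax(counts[g]))] if counts[g].sum() else "-"
            for g, lab in enumerate(labels)
        }
    return SDPResult(
        mi=mi,
        z=z,
        scored_columns=scored,
        ranked_columns=ranked,
        b_curve=b_curve,
        cutoff_l=cutoff_l,
        sdps=sdps,
        group_residues=group_residues,
    )


def null_z_pool(null_mi: np.ndarray) -> np.ndarray:
    """Pooled self-standardized shuffle scores, for the empirical tail option."""
    mean, sd = null_mi.mean(axis=0), null_mi.std(axis=0, ddof=1)
    ok = sd > 0
    return ((null_mi[:, ok] - mean[ok]) / sd[ok]).ravel()
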