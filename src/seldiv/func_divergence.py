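"""Type-I and Type-II functional divergence between two clades of a protein family.

Type-I divergence (rate decoupling after duplication/speciation) follows the
classical two-state mixture on per-site substitution counts: within each
cluster, the per-site number of changes is inferred by Fitch parsimony on the
cluster subtree; a fraction theta_I of sites draw independent gamma(alpha,
alpha) rates in the two clusters, the remainder share one rate. The marginal
of a gamma-Poisson is negative binomial, and the shared-rate case gives a
bivariate negative binomial, so the per-site likelihood is

    L_k = theta * NB(x1; alpha, D1) * NB(x2; alpha, D2)
        + (1 - theta) * BNB(x1, x2; alpha, D1, D2).

theta_I, alpha, and the cluster mean counts D1, D2 are estimated by maximum
likelihood; the standard error comes from the observed Fisher information,
the LRT compares against theta_I = 0, and Q_k is the posterior that site k is
in the rate-decoupled state. Sites with Q_k above a threshold are the
critical amino acid sites (CAAS).

Type-II divergence (radical property shifts at otherwise conserved sites) is
a closed-form estimator: among sites monomorphic within both clusters, those
whose cluster-ancestral states differ are classified radical or conserved by
an amino-acid property partition; with p_r0 the background probability of a
radical change, theta_II = (pi_R - p_r0) / (1 - p_r0), which can be negative
when radical differences are rarer than background.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy import optimize, stats
from scipy.special import gammaln, logsumexp

from .seqio import GAP, GroupAssignment, ProteinAlignment

logger = logging.getLogger(__name__)

_ALPHA_MIN, _ALPHA_MAX = 0.05, 100.0


# ---------------------------------------------------------------------------
# amino-acid property partitions


@dataclass(frozen=True)
class PropertyPartition:
    """A named partition of the 20 amino acids into property groups."""

    name: str
    groups: tuple[frozenset[str], ...]

    def __post_init__(self) -> None:
        all_aa = set("ACDEFGHIKLMNPQRSTVWY")
        seen: set[str] = set()
        for g in self.groups:
            if seen & g:
                raise ValueError(f"overlapping property groups in {self.name}")
            seen |= g
        if seen != all_aa:
            raise ValueError(f"partition {self.name} does not cover the 20 amino acids")

    def group_of(self, aa: str) -> int:
        for k, g in enumerate(self.groups):
            if aa in g:
                return k
        raise KeyError(f"not a standard amino acid: {aa!r}")

    def is_radical(self, a: str, b: str) -> bool:
        """True when a->b crosses property groups."""
        return self.group_of(a) != self.group_of(b)


CHARGE = PropertyPartition(
    "charge",
    (
        frozenset("KRH"),  # positive
        frozenset("DE"),  # negative
        frozenset("ACFGILMNPQSTVWY"),  # neutral
    ),
)
POLARITY = PropertyPartition(
    "polarity",
    (frozenset("STYCNQDEKRH"), frozenset("AGVLIPFMW")),
)
HYDROPHOBICITY = PropertyPartition(
    "hydrophobicity",
    (frozenset("AVLIPFMWC"), frozenset("GSTYNQ"), frozenset("DEKRH")),
)
PARTITIONS = {p.name: p for p in (CHARGE, POLARITY, HYDROPHOBICITY)}


# ---------------------------------------------------------------------------
# Fitch parsimony on cluster subtrees


def _subtree_for(tree: dendropy.Tree, leaf_ids: list[str]) -> dendropy.Tree:
    labels = {t.label for t in tree.taxon_namespace}
    missing = sorted(set(leaf_ids) - labels)
    if missing:
        raise ValueError(f"cluster members not in tree: {missing}")
    sub = tree.extract_tree_with_taxa_labels(leaf_ids)
    return sub

def _fitch_column(tree: dendropy.Tree, state_of: dict[str, str]) -> tuple[int, frozenset[str]]:
    """Minimum changes and root state set; missing leaves are skipped."""
    sets: dict[int, frozenset[str] | None] = {}
    changes = 0
    root = None
    for node in tree.postorder_node_iter():
        root = node
        if node.is_leaf():
            aa = state_of.get(node.taxon.label)
            sets[id(node)] = None if aa is None else frozenset((aa,))
            continue
        child_sets = [sets[id(c)] for c in node.child_nodes() if sets[id(c)] is not None]
        if not child_sets:
            sets[id(node)] = None
            continue
        inter = frozenset.intersection(*child_sets)
        if inter:
            sets[id(node)] = inter
        else:
            # polytomy-safe Fitch step: changes = children-with-data minus the
            # largest number of them agreeing on a state (1 for bifurcations)
            union = frozenset.union(*child_sets)
            agree = max(sum(1 for cs in child_sets if s in cs) for s in union)
            sets[id(node)] = union
            changes += len(child_sets) - agree
    rootset = sets[id(root)] or frozenset()
    return changes, rootset


def fitch_site_changes(aln: ProteinAlignment, subtree: dendropy.Tree) -> np.ndarray:
    """Per-column minimum number of state changes on ``subtree`` (Fitch).

    Gap/X characters are missing data; a column observed in fewer than two
    leaves contributes zero changes.
    """
    leaves = [lf.taxon.label for lf in subtree.leaf_node_iter()]
    missing = sorted(set(leaves) - set(aln.ids))
    if missing:
        raise ValueError(f"subtree leaves missing from alignment: {missing}")
    if len(leaves) < 2:
        raise ValueError("subtree needs at least 2 leaves")
    rows = {lab: aln.row(lab) for lab in leaves}
    out = np.zeros(aln.n_cols, dtype=int)
    for col in range(aln.n_cols):
        state_of = {
            lab: rows[lab][col]
            for lab in leaves
            if rows[lab][col] not in (GAP, "X")
        }
        if len(state_of) < 2:
            continue
        out[col], _ = _fitch_column(subtree, state_of)
    return out


def ancestral_states(aln: ProteinAlignment, subtree: dendropy.Tree) -> list[str | None]:
    """Fitch root state per column; ties broken by cluster consensus, then A-Z.

    Returns ``None`` for columns with no observed residue in the cluster.
    """
    leaves = [lf.taxon.label for lf in subtree.leaf_node_iter()]
    missing = sorted(set(leaves) - set(aln.ids))
    if missing:
        raise ValueError(f"subtree leaves missing from alignment: {missing}")
    rows = {lab: aln.row(lab) for lab in leaves}
    out: list[str | None] = []
    for col in range(aln.n_cols):
        state_of = {
            lab: rows[lab][col]
            for lab in leaves
            if rows[lab][col] not in (GAP, "X")
        }
        if not state_of:
            out.append(None)
            continue
        if len(state_of) == 1:
            out.append(next(iter(state_of.values())))
            continue
        _, rootset = _fitch_column(subtree, state_of)
        if len(rootset) == 1:
            out.append(next(iter(rootset)))
            continue
        counts = {s: sum(1 for v in state_of.values() if v == s) for s in rootset}
        top = max(counts.values())
        out.append(min(s for s, c in counts.items() if c == top))
    return out


# ---------------------------------------------------------------------------
# Type-I: gamma-Poisson rate-decoupling mixture


@dataclass
class ChangeCountTable:
    """Per-site substitution counts for exactly two clusters."""

    counts: np.ndarray  # (n_sites, 2) integers
    labels: tuple[str, str]

    def __post_init__(self) -> None:
        x = np.asarray(self.counts)
        if x.ndim != 2 or x.shape[1] != 2:
            raise ValueError("counts must be (n_sites, 2)")
        if (x < 0).any():
            raise ValueError("change counts must be non-negative")
        self.counts = x.astype(float)

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]


def change_count_table(
    aln: ProteinAlignment, tree: dendropy.Tree, clusters: GroupAssignment
) -> ChangeCountTable:
    """Fitch change counts per site within each of the two cluster subtrees."""
    labels = clusters.labels()
    if len(labels) != 2:
        raise ValueError(f"exactly 2 clusters supported, got {labels}")
    cols = []
    for lab in labels:
        sub = _subtree_for(tree, clusters.members(lab))
        cols.append(fitch_site_changes(aln, sub))
    return ChangeCountTable(np.stack(cols, axis=1), (labels[0], labels[1]))


def _log_nb(x: np.ndarray, alpha: float, d: float) -> np.ndarray:
    """log pmf of the gamma(alpha, alpha)-Poisson (negative binomial, mean d)."""
    return (
        gammaln(x + alpha)
        - gammaln(alpha)
        - gammaln(x + 1)
        + alpha * math.log(alpha / (alpha + d))
        + x * math.log(d / (alpha + d))
    )


def _log_bnb(x1: np.ndarray, x2: np.ndarray, alpha: float, d1: float, d2: float) -> np.ndarray:
    """log pmf of the shared-rate bivariate gamma-Poisson."""
    s = x1 + x2
    return (
        gammaln(s + alpha)
        - gammaln(alpha)
        - gammaln(x1 + 1)
        - gammaln(x2 + 1)
        + x1 * math.log(d1)
        + x2 * math.log(d2)
        + alpha * math.log(alpha)
        - (s + alpha) * math.log(alpha + d1 + d2)
    )


@dataclass
class TypeIResult:
    """theta_I with SE, the LRT against theta_I = 0, and per-site posteriors Q_k."""

    theta1: float
    se: float
    lrt: float
    p_value: float
    alpha: float
    d1: float
    d2: float
    qk: np.ndarray
    lnL: float
    boundary: bool = False
    labels: tuple[str, str] = ("cluster1", "cluster2")


def _type1_loglik(theta: float, alpha: float, d1: float, d2: float, x1, x2) -> np.ndarray:
    ind = _log_nb(x1, alpha, d1) + _log_nb(x2, alpha, d2)
    joint = _log_bnb(x1, x2, alpha, d1, d2)
    if theta <= 0:
        return joint
    if theta >= 1:
        return ind
    return logsumexp(
        np.stack([ind + math.log(theta), joint + math.log1p(-theta)]), axis=0
    )


def fit_type1(counts: ChangeCountTable) -> TypeIResult:
    """ML fit of the Type-I rate-decoupling mixture to per-site change counts."""
    x1, x2 = counts.counts[:, 0], counts.counts[:, 1]
    if x1.sum() == 0 or x2.sum() == 0:
        raise ValueError("a cluster has zero changes at every site: no rate information")
    if counts.n_sites < 20:
        warnings.warn(
            f"only {counts.n_sites} sites: theta_I estimate will be unstable",
            stacklevel=2,
        )

    d1_0, d2_0 = max(x1.mean(), 1e-3), max(x2.mean(), 1e-3)

    def unpack(z):
        theta = 1.0 / (1.0 + math.exp(-z[0]))
        return theta, math.exp(z[1]), math.exp(z[2]), math.exp(z[3])

    def neg(z, fix_theta=None):
        if fix_theta is None:
            theta, alpha, d1, d2 = unpack(z)
        else:
            theta = fix_theta
            alpha, d1, d2 = math.exp(z[0]), math.exp(z[1]), math.exp(z[2])
        return -float(_type1_loglik(theta, alpha, d1, d2, x1, x2).sum())

    la, lb = math.log(_ALPHA_MIN), math.log(_ALPHA_MAX)
    ld = (math.log(1e-4), math.log(1e3))
    # null: theta = 0
    z0 = np.array([0.0, math.log(d1_0), math.log(d2_0)])
    res0 = optimize.minimize(
        neg, z0, args=(0.0,), method="L-BFGS-B", bounds=[(la, lb), ld, ld]
    )
    lnL0 = -res0.fun

    best = None
    for th0 in (0.2, 0.6):
        z1 = np.array([math.log(th0 / (1 - th0)), res0.x[0], res0.x[1], res0.x[2]])
        res = optimize.minimize(
            neg, z1, method="L-BFGS-B", bounds=[(-12, 12), (la, lb), ld, ld]
        )
        if best is None or res.fun < best.fun:
            best = res
    theta, alpha, d1, d2 = unpack(best.x)
    lnL1 = -best.fun
    lrt = max(2.0 * (lnL1 - lnL0), 0.0)
    boundary = theta < 1e-4 or theta > 1 - 1e-4

    se = _theta_se(theta, alpha, d1, d2, x1, x2)
    qk = _type1_qk(theta, alpha, d1, d2, x1, x2)
    return TypeIResult(
        theta1=theta,
        se=se,
        lrt=lrt,
        p_value=float(stats.chi2.sf(lrt, 1)),
        alpha=alpha,
        d1=d1,
        d2=d2,
        qk=qk,
        lnL=lnL1,
        boundary=boundary,
        labels=counts.labels,
    )


def _type1_qk(theta, alpha, d1, d2, x1, x2) -> np.ndarray:
    if theta <= 0:
        return np.zeros_like(x1, dtype=float)
    if theta >= 1:
        return np.ones_like(x1, dtype=float)
    li = _log_nb(x1, alpha, d1) + _log_nb(x2, alpha, d2) + math.log(theta)
    lj = _log_bnb(x1, x2, alpha, d1, d2) + math.log1p(-theta)
    return np.exp(li - np.logaddexp(li, lj))


def _theta_se(theta, alpha, d1, d2, x1, x2) -> float:
    """SE of theta_I from the observed Fisher information (4x4 numerical Hessian)."""
    p0 = np.array([theta, alpha, d1, d2])
    eps = np.maximum(1e-4, 1e-4 * np.abs(p0))

    def nll(p):
        th = min(max(p[0], 1e-8), 1 - 1e-8)
        a = min(max(p[1], 1e-6), 1e4)
        return -float(_type1_loglik(th, a, max(p[2], 1e-8), max(p[3], 1e-8), x1, x2).sum())

    n = 4
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps[i]
            ej = np.zeros(n); ej[j] = eps[j]
            H[i, j] = H[j, i] = (
                nll(p0 + ei + ej) - nll(p0 + ei - ej) - nll(p0 - ei + ej) + nll(p0 - ei - ej)
            ) / (4 * eps[i] * eps[j])
    try:
        cov = np.linalg.inv(H)
        var = cov[0, 0]
        if var > 0:
            return float(math.sqrt(var))
    except np.linalg.LinAlgError:
        pass
    logger.info("Fisher information not invertible; theta_I SE unavailable")
    return math.nan


def type1_caas(result: TypeIResult, q_threshold: float = 0.9) -> list[tuple[int, float]]:
    """Sites with Q_k above the threshold, sorted by descending Q_k."""
    hits = [(int(k), float(q)) for k, q in enumerate(result.qk) if q > q_threshold]
    hits.sort(key=lambda t: (-t[1], t[0]))
    return hits


# ---------------------------------------------------------------------------
# Type-II: radical property shifts between cluster ancestors


@dataclass
class TypeIIResult:
    """theta_II with SE and a per-site classification.

    ``site_class[k]`` is one of ``no_difference``, ``conserved_difference``,
    ``radical_difference``, ``not_applicable``. theta_II is NaN (undefined)
    when no applicable site differs between the cluster ancestors.
    """

    theta2: float
    se: float
    p_r0: float
    pi_r: float
    n_applicable: int
    n_differing: int
    site_class: list[str]
    qk: np.ndarray
    labels: tuple[str, str] = ("cluster1", "cluster2")

    @property
    def defined(self) -> bool:
        return not math.isnan(self.theta2)


def fit_type2(
    aln: ProteinAlignment,
    tree: dendropy.Tree,
    clusters: GroupAssignment,
    partition: PropertyPartition = CHARGE,
) -> TypeIIResult:
    """Closed-form Type-II estimator from cluster-ancestral residue pairs.

    Applicable sites are monomorphic within both clusters; among those whose
    ancestral residues differ, pi_R is the radical fraction. The background
    radical probability p_r0 pools within-cluster substitution events
    (consensus residue vs each other observed residue) over non-applicable
    sites; theta_II = (pi_R - p_r0) / (1 - p_r0); SE by the binomial delta
    method with p_r0 treated as known.
    """
    labels = clusters.labels()
    if len(labels) != 2:
        raise ValueError(f"exactly 2 clusters supported, got {labels}")
    subs = [_subtree_for(tree, clusters.members(lab)) for lab in labels]
    changes = [fitch_site_changes(aln, s) for s in subs]
    ancestors = [ancestral_states(aln, s) for s in subs]
    member_rows = [
        [aln.row(m) for m in clusters.members(lab)] for lab in labels
    ]

    site_class: list[str] = []
    n_rad = n_diff = n_app = 0
    rad_events = tot_events = 0
    for col in range(aln.n_cols):
        a1, a2 = ancestors[0][col], ancestors[1][col]
        applicable = changes[0][col] == 0 and changes[1][col] == 0 and a1 and a2
        if applicable:
            n_app += 1
            if a1 == a2:
                site_class.append("no_difference")
            else:
                n_diff += 1
                if partition.is_radical(a1, a2):
                    site_class.append("radical_difference")
                    n_rad += 1
                else:
                    site_class.append("conserved_difference")
        else:
            site_class.append("not_applicable")
            # pool within-cluster events: consensus vs each other residue
            for c, rows in enumerate(member_rows):
                residues = [r[col] for r in rows if r[col] not in (GAP, "X")]
                if len(set(residues)) < 2:
                    continue
                counts = {s: residues.count(s) for s in set(residues)}
                consensus = min(
                    (s for s in counts if counts[s] == max(counts.values()))
                )
                for other in counts:
                    if other == consensus:
                        continue
                    tot_events += 1
                    rad_events += partition.is_radical(consensus, other)

    p_r0 = rad_events / tot_events if tot_events else 0.5
    if n_diff == 0:
        return TypeIIResult(
            theta2=math.nan, se=math.nan, p_r0=p_r0, pi_r=math.nan,
            n_applicable=n_app, n_differing=0, site_class=site_class,
            qk=np.zeros(aln.n_cols), labels=(labels[0], labels[1]),
        )
    pi_r = n_rad / n_diff
    theta2 = (pi_r - p_r0) / (1.0 - p_r0)
    se = math.sqrt(pi_r * (1 - pi_r) / n_diff) / (1.0 - p_r0) if n_diff else math.nan
    qk = np.zeros(aln.n_cols)
    if theta2 > 0:
        q_rad = theta2 / (theta2 + (1 - theta2) * p_r0) if p_r0 > 0 else 1.0
        for col, cls in enumerate(site_class):
            if cls == "radical_difference":
                qk[col] = q_rad
    return TypeIIResult(
        theta2=theta2, se=se, p_r0=p_r0, pi_r=pi_r,
        n_applicable=n_app, n_differing=n_diff, site_class=site_class,
        qk=qk, labels=(labels[0], labels[1]),
    )
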