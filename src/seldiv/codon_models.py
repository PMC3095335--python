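"""Codon substitution models and maximum-likelihood tests of positive selection.

The model family is the Goldman-Yang style Markov process on the 61 sense
codons of the standard code: codons one nucleotide apart exchange at rate
pi_j * kappa^[transition] * omega^[nonsynonymous], all other entries are zero,
and the generator is scaled so branch lengths are expected substitutions per
codon. Site-to-site variation in omega = dN/dS is modelled as a finite
mixture:

* M0 - a single omega shared by all sites;
* M3 - K discrete omega classes with free proportions;
* M7 - omega ~ Beta(p, q) on (0, 1), discretized into 10 equal-probability
  classes at bin medians;
* M8 - a proportion p0 of M7-style beta sites plus a proportion 1 - p0 with
  omega_s >= 1 (the positive-selection class).

Likelihoods come from Felsenstein pruning with per-node rescaling, vectorized
over mixture classes and alignment site patterns. Nested pairs (M0 vs M3,
M7 vs M8, one-ratio vs free-ratio branch models) are compared with chi-square
likelihood-ratio tests, and sites are assigned to classes by naive empirical
Bayes (NEB) posteriors; sites with high posterior mass on an omega > 1 class
are the positive-selection candidates.

Optimization is a deterministic warm-start cascade: M0 is fitted jointly
(branch lengths, kappa, omega) and seeds the branch lengths of the richer
models, which then alternate bounded L-BFGS-B blocks over model parameters
and branch lengths; M8 starts from the fitted M7, which guarantees its
log-likelihood can only improve on the null. Extra seeded random restarts are
available through ``FitSettings.n_starts``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import dendropy
import numpy as np
from scipy import linalg, optimize, stats
from scipy.special import logsumexp

from ._gencode import CODON_INDEX, CODON_TO_AA, SENSE_CODONS, STOP_CODONS, is_transition
from .seqio import GAP, CodonAlignment

N_CODONS = 61
_T_MIN, _T_MAX = 1e-7, 25.0
_T_UNIDENT = 1e-5  # below this a branch carries no information about its omega
_KAPPA_MIN, _KAPPA_MAX = 0.05, 60.0
_OMEGA_MIN, _OMEGA_MAX = 1e-6, 60.0
_BETA_MIN, _BETA_MAX = 5e-3, 99.0

# ordered pairs of sense codons one nucleotide apart
_pi_idx, _pj_idx, _ts_flag, _syn_flag = [], [], [], []
for _i, _ci in enumerate(SENSE_CODONS):
    for _j, _cj in enumerate(SENSE_CODONS):
        if _i == _j:
            continue
        diffs = [(a, b) for a, b in zip(_ci, _cj) if a != b]
        if len(diffs) != 1:
            continue
        _pi_idx.append(_i)
        _pj_idx.append(_j)
        _ts_flag.append(is_transition(*diffs[0]))
        _syn_flag.append(CODON_TO_AA[_ci] == CODON_TO_AA[_cj])
_PI = np.array(_pi_idx)
_PJ = np.array(_pj_idx)
_TS = np.array(_ts_flag)
_SYN = np.array(_syn_flag)


class ModelError(ValueError):
    """Invalid model parameters or incompatible inputs."""


@dataclass
class CodonModel:
    """A GY94-style codon model: kappa, an omega mixture, and codon frequencies."""

    kappa: float
    omega_classes: list[tuple[float, float]]  # (proportion, omega)
    codon_freqs: np.ndarray
    freq_mode: str = "F3x4"
    beta_params: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ModelError(f"kappa must be positive, got {self.kappa}")
        props = np.array([p for p, _ in self.omega_classes])
        omegas = np.array([w for _, w in self.omega_classes])
        if abs(props.sum() - 1.0) > 1e-9:
            raise ModelError(f"omega-class proportions sum to {props.sum()}, not 1")
        if (omegas < 0).any():
            raise ModelError("omega values must be >= 0")
        pi = np.asarray(self.codon_freqs, dtype=float)
        if pi.shape != (N_CODONS,) or abs(pi.sum() - 1.0) > 1e-9 or (pi < 0).any():
            raise ModelError("codon_freqs must be 61 non-negative values summing to 1")
        self.codon_freqs = pi

    @property
    def proportions(self) -> np.ndarray:
        return np.array([p for p, _ in self.omega_classes])

    @property
    def omegas(self) -> np.ndarray:
        return np.array([w for _, w in self.omega_classes])


def codon_frequencies(aln: CodonAlignment, mode: str = "F3x4") -> np.ndarray:
    """Equilibrium codon frequencies: equal, F1x4, or F3x4 (PAML conventions).

    F3x4 multiplies the observed nucleotide frequencies at each codon
    position; stop codons are excluded and the result renormalized. A small
    floor keeps unobserved codons reachable.
    """
    if mode == "equal":
        return np.full(N_CODONS, 1.0 / N_CODONS)
    counts = np.zeros((3, 4))
    order = "TCAG"
    for rec in aln.records:
        for k in range(0, len(rec.seq), 3):
            codon = rec.seq[k : k + 3]
            if GAP in codon:
                continue
            for pos, nt in enumerate(codon):
                if nt in order:
                    counts[pos, order.index(nt)] += 1
    if mode == "F1x4":
        tot = counts.sum(axis=0)
        freq = tot / tot.sum() if tot.sum() else np.full(4, 0.25)
        pos_freq = np.tile(freq, (3, 1))
    elif mode == "F3x4":
        sums = counts.sum(axis=1, keepdims=True)
        pos_freq = np.where(sums > 0, counts / np.maximum(sums, 1), 0.25)
    else:
        raise ModelError(f"unknown codon frequency mode {mode!r}")
    pi = np.array(
        [pos_freq[0, order.index(c[0])] * pos_freq[1, order.index(c[1])] * pos_freq[2, order.index(c[2])]
         for c in SENSE_CODONS]
    )
    pi = np.maximum(pi, 1e-8)
    return pi / pi.sum()


def codon_rate_matrix(kappa: float, omega: float, codon_freqs: np.ndarray) -> np.ndarray:
    """Scaled 61x61 GY94 generator (mean rate 1 at stationarity)."""
    if kappa <= 0:
        raise ModelError(f"kappa must be positive, got {kappa}")
    if omega < 0:
        raise ModelError(f"omega must be non-negative, got {omega}")
    pi = np.asarray(codon_freqs, dtype=float)
    Q = np.zeros((N_CODONS, N_CODONS))
    rates = pi[_PJ] * np.where(_TS, kappa, 1.0) * np.where(_SYN, 1.0, omega)
    Q[_PI, _PJ] = rates
    Q[np.diag_indices(N_CODONS)] = -Q.sum(axis=1)
    mu = -(pi * np.diag(Q)).sum()
    if mu > 0:
        Q /= mu
    return Q


def transition_matrix(Q: np.ndarray, t: float) -> np.ndarray:
    """P(t) = expm(Q t); rows sum to 1, identity at t = 0."""
    if t < 0:
        raise ModelError(f"branch length must be >= 0, got {t}")
    return linalg.expm(Q * t)


class _SpectralQ:
    """Eigendecomposition of a reversible generator for cheap P(t) evaluation.

    With Q_ij = pi_j s_ij (s symmetric), B = Pi^1/2 Q Pi^-1/2 is symmetric;
    P(t) = W diag(exp(lambda t)) Z with W = Pi^-1/2 V and Z = V^T Pi^1/2.
    """

    def __init__(self, Q: np.ndarray, pi: np.ndarray):
        sq = np.sqrt(pi)
        B = sq[:, None] * Q / sq[None, :]
        lam, V = np.linalg.eigh((B + B.T) / 2)
        self.lam = lam
        self.W = V / sq[:, None]
        self.Z = V.T * sq[None, :]

    def propagators(self, t: np.ndarray) -> np.ndarray:
        """P(t_b) for a vector of branch lengths -> (n_branch, 61, 61)."""
        E = np.exp(np.outer(t, self.lam))
        P = (self.W[None, :, :] * E[:, None, :]) @ self.Z
        np.maximum(P, 0.0, out=P)
        return P


class PruningEngine:
    """Felsenstein pruning over a codon alignment and a fixed tree topology.

    Site patterns are compressed; partial likelihoods are rescaled per node.
    Gap ('---') and ambiguous codons are missing data (partial vector of
    ones). Branches are indexed in postorder; ``branch_labels[b]`` is the leaf
    label for terminal branches or an internal node tag.
    """

    def __init__(self, aln: CodonAlignment, tree: dendropy.Tree):
        # a basal bifurcation leaves the two root edges confounded under a
        # reversible stationary model; analyze the unrooted (trifurcating) tree
        if len(tree.seed_node.child_nodes()) == 2 and sum(
            1 for _ in tree.leaf_node_iter()
        ) > 2:
            tree = tree.clone(depth=1)
            tree.deroot()
        leaf_labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        aln_ids = sorted(aln.ids)
        if leaf_labels != aln_ids:
            only_tree = sorted(set(leaf_labels) - set(aln_ids))
            only_aln = sorted(set(aln_ids) - set(leaf_labels))
            raise ModelError(
                f"tree/alignment mismatch: only in tree {only_tree}, only in alignment {only_aln}"
            )
        row_of = {rec.id: i for i, rec in enumerate(aln.records)}
        n_cols = aln.n_codon_cols

        # codon-state matrix, -1 = missing
        states = np.full((aln.n_seqs, n_cols), -1, dtype=np.int64)
        for i, rec in enumerate(aln.records):
            for col in range(n_cols):
                codon = rec.seq[3 * col : 3 * col + 3]
                if codon == GAP * 3 or "N" in codon:
                    continue
                if codon in STOP_CODONS:
                    raise ModelError(f"stop codon {codon} at column {col} in {rec.id!r}")
                states[i, col] = CODON_INDEX[codon]

        pat, inverse, counts = np.unique(
            states.T, axis=0, return_inverse=True, return_counts=True
        )
        self.patterns = pat.T  # (n_seqs, n_patterns)
        self.pattern_of_site = inverse.ravel()
        self.pattern_counts = counts.astype(float)
        self.n_sites = n_cols
        self.n_patterns = self.patterns.shape[1]

        # flatten tree into postorder structure
        self.branch_labels: list[str] = []
        self.init_lengths: list[float] = []
        node_id: dict[int, int] = {}
        self.nodes: list[tuple[int, list[tuple[int | None, int, int | None]]]] = []
        internal_counter = 0
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                continue
            children = []
            for child in node.child_nodes():
                length = child.edge.length if child.edge.length is not None else 0.1
                bidx = len(self.branch_labels)
                if child.is_leaf():
                    self.branch_labels.append(child.taxon.label)
                    children.append((None, bidx, row_of[child.taxon.label]))
                else:
                    tag = child.label or f"node{node_id[id(child)]}"
                    self.branch_labels.append(str(tag))
                    children.append((node_id[id(child)], bidx, None))
                self.init_lengths.append(max(float(length), _T_MIN))
            node_id[id(node)] = internal_counter
            self.nodes.append((internal_counter, children))
            internal_counter += 1
        if not self.nodes:
            raise ModelError("tree must contain at least one internal node")
        self.root_id = self.nodes[-1][0]
        self.n_branches = len(self.branch_labels)

    def pattern_class_loglik(self, Ps: np.ndarray, pi: np.ndarray) -> np.ndarray:
        """log L(pattern | class) for Ps of shape (n_class, n_branch, 61, 61)."""
        nclass = Ps.shape[0]
        npat = self.n_patterns
        store: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        for nid, children in self.nodes:
            arr = np.ones((nclass, N_CODONS, npat))
            logscale = np.zeros((nclass, npat))
            for child_id, bidx, leaf_row in children:
                P = Ps[:, bidx]
                if leaf_row is not None:
                    st = self.patterns[leaf_row]
                    miss = st < 0
                    contrib = P[:, :, np.where(miss, 0, st)]
                    if miss.any():
                        contrib = contrib.copy()
                        contrib[:, :, miss] = 1.0
                else:
                    carr, cls = store.pop(child_id)
                    contrib = P @ carr
                    logscale += cls
                arr = arr * contrib
            smax = arr.max(axis=1)
            np.maximum(smax, 1e-300, out=smax)
            arr /= smax[:, None, :]
            logscale += np.log(smax)
            store[nid] = (arr, logscale)
        root_arr, root_ls = store[self.root_id]
        L = np.einsum("cip,i->cp", root_arr, pi)
        with np.errstate(divide="ignore"):
            return np.log(np.maximum(L, 1e-300)) + root_ls

    def mixture_loglik(
        self, Ps: np.ndarray, pi: np.ndarray, log_props: np.ndarray
    ) -> tuple[float, np.ndarray]:
        """Total lnL and per-pattern lnL under a class mixture."""
        cll = self.pattern_class_loglik(Ps, pi)
        pat_ll = logsumexp(cll + log_props[:, None], axis=0)
        return float(pat_ll @ self.pattern_counts), pat_ll

    def expand(self, per_pattern: np.ndarray) -> np.ndarray:
        """Map a per-pattern vector/matrix (last axis = patterns) to sites."""
        return per_pattern[..., self.pattern_of_site]


@dataclass
class FitSettings:
    """Optimizer controls for site- and branch-model fits."""

    freq_mode: str = "F3x4"
    m3_classes: int = 3
    n_beta_classes: int = 10
    tol: float = 1e-6
    round_tol: float = 0.02
    max_rounds: int = 3
    maxiter_joint: int = 300
    maxiter_model: int = 60
    maxiter_branch: int = 30
    n_starts: int = 1
    seed: int = 0


@dataclass
class SiteModelFit:
    """A fitted site model: lnL, parameter estimates, and NEB site posteriors."""

    model_name: str
    lnL: float
    model: CodonModel
    branch_lengths: dict[str, float]
    n_params: int
    site_posteriors: np.ndarray  # (n_sites, n_classes), rows sum to 1
    site_loglik: np.ndarray

    @property
    def pss(self) -> list[tuple[int, float]]:
        """(site, posterior that omega > 1) for sites with any mass on omega > 1."""
        sel = self.model.omegas > 1.0
        if not sel.any():
            return []
        p = self.site_posteriors[:, sel].sum(axis=1)
        return [(int(h), float(p[h])) for h in range(len(p))]


@dataclass(frozen=True)
class LRTResult:
    two_delta_l: float
    df: int
    p_value: float


@dataclass
class BranchModelFit:
    """One-ratio or free-ratio branch model fit."""

    mode: str
    lnL: float
    kappa: float
    branch_lengths: dict[str, float]
    omega_by_branch: dict[str, float]
    n_params: int
    unidentifiable: list[str] = field(default_factory=list)

    @property
    def flagged_branches(self) -> list[str]:
        return [
            b
            for b, w in self.omega_by_branch.items()
            if w > 1.0 and b not in self.unidentifiable
        ]


def discretize_beta(p: float, q: float, k: int = 10) -> np.ndarray:
    """k equal-probability omega classes at beta bin medians on (0, 1)."""
    quantiles = (2 * np.arange(k) + 1) / (2 * k)
    return np.clip(stats.beta.ppf(quantiles, p, q), 1e-8, 1 - 1e-12)


def _eigs_for(kappa: float, omegas: Sequence[float], pi: np.ndarray) -> list[_SpectralQ]:
    return [_SpectralQ(codon_rate_matrix(kappa, w, pi), pi) for w in omegas]


def _build_Ps(eigs: list[_SpectralQ], t: np.ndarray) -> np.ndarray:
    return np.stack([e.propagators(t) for e in eigs])


class _ModelSpec:
    """Maps an unconstrained-ish parameter vector to (kappa, omegas, props)."""

    def __init__(self, which: str, settings: FitSettings):
        self.which = which
        self.settings = settings

    def unpack(self, x: np.ndarray) -> tuple[float, np.ndarray, np.ndarray, tuple | None]:
        kappa = math.exp(x[0])
        s = self.settings
        if self.which == "M0":
            return kappa, np.array([math.exp(x[1])]), np.array([1.0]), None
        if self.which == "M3":
            k = s.m3_classes
            omegas = np.exp(x[1 : 1 + k])
            logits = np.concatenate([x[1 + k :], [0.0]])
            props = np.exp(logits - logsumexp(logits))
            return kappa, omegas, props, None
        if self.which == "M7":
            p, q = math.exp(x[1]), math.exp(x[2])
            omegas = discretize_beta(p, q, s.n_beta_classes)
            props = np.full(s.n_beta_classes, 1.0 / s.n_beta_classes)
            return kappa, omegas, props, (p, q)
        if self.which == "M8":
            p, q = math.exp(x[1]), math.exp(x[2])
            p0 = 1.0 / (1.0 + math.exp(-x[3]))
            omega_s = 1.0 + math.exp(x[4])
            k = s.n_beta_classes
            omegas = np.append(discretize_beta(p, q, k), omega_s)
            props = np.append(np.full(k, p0 / k), 1.0 - p0)
            return kappa, omegas, props, (p, q)
        raise ModelError(f"unknown site model {self.which!r}")

    def bounds(self) -> list[tuple[float, float]]:
        lk = (math.log(_KAPPA_MIN), math.log(_KAPPA_MAX))
        lw = (math.log(_OMEGA_MIN), math.log(_OMEGA_MAX))
        lb = (math.log(_BETA_MIN), math.log(_BETA_MAX))
        if self.which == "M0":
            return [lk, lw]
        if self.which == "M3":
            k = self.settings.m3_classes
            return [lk] + [lw] * k + [(-12.0, 12.0)] * (k - 1)
        if self.which == "M7":
            return [lk, lb, lb]
        if self.which == "M8":
            return [lk, lb, lb, (-14.0, 14.0), (math.log(1e-4), math.log(_OMEGA_MAX - 1))]
        raise ModelError(self.which)

    def n_free(self) -> int:
        return {"M0": 1, "M3": 2 * self.settings.m3_classes - 1, "M7": 2, "M8": 4}[self.which]

    def starts(self, m0_omega: float, m7_x: np.ndarray | None, kappa0: float) -> list[np.ndarray]:
        lk = math.log(kappa0)
        w0 = min(max(m0_omega, 1e-3), 5.0)
        if self.which == "M0":
            return [np.array([lk, math.log(w0)])]
        if self.which == "M3":
            k = self.settings.m3_classes
            base = np.array(
                [lk]
                + [math.log(max(w0 * f, 1e-5)) for f in np.geomspace(0.2, 3.0, k)]
                + [0.0] * (k - 1)
            )
            wide = base.copy()
            wide[1 : 1 + k] = [math.log(v) for v in np.geomspace(0.01, 2.5, k)]
            return [base, wide]
        if self.which == "M7":
            p = max(0.3, 2 * w0)
            q = max(0.3, 2 * (1 - min(w0, 0.95)))
            return [np.array([lk, math.log(p), math.log(q)])]
        if self.which == "M8":
            # warm-started from a fitted M7, a single near-null start suffices;
            # otherwise also try a start with real mass on the selection class
            configs = ((0.99, 1.8),) if m7_x is not None else ((0.99, 1.8), (0.9, 1.3))
            head = m7_x.copy() if m7_x is not None else np.array([lk, 0.0, 0.0])
            return [
                np.concatenate([head, [math.log(p0 / (1 - p0)), math.log(ws - 1)]])
                for p0, ws in configs
            ]
        raise ModelError(self.which)


def _minimize(fun, x0, bounds, maxiter):
    res = optimize.minimize(
        fun, x0, method="L-BFGS-B", bounds=bounds, options={"maxiter": maxiter}
    )
    return res.x, -res.fun


def site_log_likelihoods(
    aln: CodonAlignment, tree: dendropy.Tree, model: CodonModel
) -> tuple[np.ndarray, float]:
    """Per-site log-likelihoods and their total for a fixed model and tree.

    Branch lengths come from the tree. For a single-taxon tree there are no
    branches and each site's likelihood is the stationary probability of its
    observed codon (missing data contributes zero).
    """
    if sum(1 for _ in tree.leaf_node_iter()) == 1 and aln.n_seqs == 1:
        rec = aln.records[0]
        ll = np.zeros(aln.n_codon_cols)
        for col in range(aln.n_codon_cols):
            codon = rec.seq[3 * col : 3 * col + 3]
            if codon == GAP * 3 or "N" in codon:
                continue
            ll[col] = math.log(model.codon_freqs[CODON_INDEX[codon]])
        return ll, float(ll.sum())
    engine = PruningEngine(aln, tree)
    t = np.array(engine.init_lengths)
    eigs = _eigs_for(model.kappa, model.omegas, model.codon_freqs)
    Ps = _build_Ps(eigs, t)
    total, pat_ll = engine.mixture_loglik(Ps, model.codon_freqs, np.log(model.proportions))
    return engine.expand(pat_ll), total


def _posteriors(
    engine: PruningEngine, Ps: np.ndarray, pi: np.ndarray, props: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    cll = engine.pattern_class_loglik(Ps, pi)
    log_joint = cll + np.log(props)[:, None]
    pat_ll = logsumexp(log_joint, axis=0)
    post = np.exp(log_joint - pat_ll[None, :])
    total = float(pat_ll @ engine.pattern_counts)
    return engine.expand(post).T, engine.expand(pat_ll), total


def fit_site_model(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    which: str = "M0",
    settings: FitSettings | None = None,
    init_fit: SiteModelFit | None = None,
) -> SiteModelFit:
    """Maximum-likelihood fit of a codon site model.

    Branch lengths, kappa, and the omega distribution are all optimized.
    ``init_fit`` (typically the M0 or M7 fit) warm-starts branch lengths;
    M8 additionally warm-starts its beta parameters from a fresh M7 fit when
    none is supplied.
    """
    settings = settings or FitSettings()
    engine = PruningEngine(aln, tree)
    pi = codon_frequencies(aln, settings.freq_mode)
    spec = _ModelSpec(which, settings)
    log_t_bounds = (math.log(_T_MIN), math.log(_T_MAX))

    def model_ll(x_model: np.ndarray, t: np.ndarray) -> float:
        kappa, omegas, props, _ = spec.unpack(x_model)
        Ps = _build_Ps(_eigs_for(kappa, omegas, pi), t)
        total, _ = engine.mixture_loglik(Ps, pi, np.log(np.maximum(props, 1e-300)))
        return total

    # --- stage 1: branch lengths (and kappa/omega) from a joint M0 fit ---
    if init_fit is not None:
        t0 = np.array([init_fit.branch_lengths[b] for b in engine.branch_labels])
        kappa0 = init_fit.model.kappa
        m0_omega = float(init_fit.model.omegas @ init_fit.model.proportions)
    else:
        m0_spec = _ModelSpec("M0", settings)
        x0 = np.concatenate(
            [np.log(np.clip(engine.init_lengths, _T_MIN, _T_MAX)), [math.log(2.0), math.log(0.3)]]
        )
        nbr = engine.n_branches

        def joint_neg(xf):
            t = np.exp(xf[:nbr])
            return -model_ll_m0(xf[nbr:], t)

        def model_ll_m0(xm, t):
            kappa, omegas, props, _ = m0_spec.unpack(xm)
            Ps = _build_Ps(_eigs_for(kappa, omegas, pi), t)
            total, _ = engine.mixture_loglik(Ps, pi, np.log(props))
            return total

        bounds = [log_t_bounds] * nbr + m0_spec.bounds()
        xbest, _ = _minimize(joint_neg, x0, bounds, settings.maxiter_joint)
        t0 = np.exp(xbest[:nbr])
        kappa0 = math.exp(xbest[nbr])
        m0_omega = math.exp(xbest[nbr + 1])
        if which == "M0":
            return _finalize_site_fit(engine, pi, spec, xbest[nbr:], t0, settings)

    # --- stage 2: alternate model-parameter and branch-length blocks ---
    m7_x = None
    if which == "M8" and init_fit is None:
        m7 = fit_site_model(aln, tree, "M7", settings)
        m7_x = np.array(
            [math.log(m7.model.kappa), math.log(m7.model.beta_params[0]), math.log(m7.model.beta_params[1])]
        )
        t0 = np.array([m7.branch_lengths[b] for b in engine.branch_labels])
    if which == "M8" and init_fit is not None and init_fit.model_name == "M7":
        m7_x = np.array(
            [
                math.log(init_fit.model.kappa),
                math.log(init_fit.model.beta_params[0]),
                math.log(init_fit.model.beta_params[1]),
            ]
        )

    starts = spec.starts(m0_omega, m7_x, kappa0)
    if settings.n_starts > 1:
        rng = np.random.default_rng(settings.seed)
        base = starts[0]
        lo = np.array([b[0] for b in spec.bounds()])
        hi = np.array([b[1] for b in spec.bounds()])
        for _ in range(settings.n_starts - 1):
            starts.append(np.clip(base + rng.normal(0, 0.5, size=base.size), lo, hi))

    best: tuple[float, np.ndarray, np.ndarray] | None = None
    for x_start in starts:
        t = t0.copy()
        x = np.clip(
            x_start, [b[0] for b in spec.bounds()], [b[1] for b in spec.bounds()]
        )
        prev = -math.inf
        for _ in range(settings.max_rounds):
            x, ll = _minimize(
                lambda xm: -model_ll(xm, t), x, spec.bounds(), settings.maxiter_model
            )
            kappa, omegas, props, _ = spec.unpack(x)
            eigs = _eigs_for(kappa, omegas, pi)
            log_props = np.log(np.maximum(props, 1e-300))

            def branch_neg(lt):
                Ps = _build_Ps(eigs, np.exp(lt))
                total, _ = engine.mixture_loglik(Ps, pi, log_props)
                return -total

            lt, ll = _minimize(
                branch_neg,
                np.log(np.clip(t, _T_MIN, _T_MAX)),
                [log_t_bounds] * engine.n_branches,
                settings.maxiter_branch,
            )
            t = np.exp(lt)
            if ll - prev < settings.round_tol:
                prev = ll
                break
            prev = ll
        if best is None or prev > best[0]:
            best = (prev, x, t)

    _, x_fit, t_fit = best
    if which == "M8" and m7_x is not None:
        # the M7 solution mapped to the p0 -> 1 boundary of M8: keeps the LRT
        # statistic non-negative even when the alternating scheme stops early
        x_bound = np.concatenate([m7_x, [14.0, math.log(0.8)]])
        ll_bound = model_ll(x_bound, t0)
        if ll_bound > best[0]:
            x_fit, t_fit = x_bound, t0
    return _finalize_site_fit(engine, pi, spec, x_fit, t_fit, settings)


def _finalize_site_fit(
    engine: PruningEngine,
    pi: np.ndarray,
    spec: _ModelSpec,
    x_model: np.ndarray,
    t: np.ndarray,
    settings: FitSettings,
) -> SiteModelFit:
    kappa, omegas, props, beta_params = spec.unpack(x_model)
    Ps = _build_Ps(_eigs_for(kappa, omegas, pi), t)
    post, site_ll, total = _posteriors(engine, Ps, pi, np.maximum(props, 1e-300))
    model = CodonModel(
        kappa=kappa,
        omega_classes=[(float(p), float(w)) for p, w in zip(props, omegas)],
        codon_freqs=pi,
        freq_mode=settings.freq_mode,
        beta_params=beta_params,
    )
    return SiteModelFit(
        model_name=spec.which,
        lnL=total,
        model=model,
        branch_lengths=dict(zip(engine.branch_labels, map(float, t))),
        n_params=engine.n_branches + 1 + spec.n_free(),
        site_posteriors=post,
        site_loglik=site_ll,
    )


_NESTED_PAIRS = {("M0", "M3"), ("M7", "M8"), ("M0", "M8"), ("one_ratio", "free_ratio")}


def likelihood_ratio_test(null_fit, alt_fit) -> LRTResult:
    """Chi-square LRT of nested model fits: 2*(lnL_alt - lnL_null) on df = dp."""
    null_name = getattr(null_fit, "model_name", getattr(null_fit, "mode", None))
    alt_name = getattr(alt_fit, "model_name", getattr(alt_fit, "mode", None))
    if (null_name, alt_name) not in _NESTED_PAIRS:
        raise ModelError(f"{null_name} is not nested in {alt_name}")
    df = alt_fit.n_params - null_fit.n_params
    if df <= 0:
        raise ModelError("alternative model has no extra parameters")
    two_dl = 2.0 * (alt_fit.lnL - null_fit.lnL)
    if two_dl < -1e-3:
        raise ModelError(
            f"alternative lnL {alt_fit.lnL:.4f} below null {null_fit.lnL:.4f}: "
            "optimization failure"
        )
    two_dl = max(two_dl, 0.0)
    return LRTResult(two_dl, df, float(stats.chi2.sf(two_dl, df)))


@dataclass(frozen=True)
class SelectedSite:
    site: int  # 0-based codon column
    posterior: float
    starred: bool  # posterior >= the high-confidence threshold


def positively_selected_sites(
    fit: SiteModelFit, high: float = 0.95, report_floor: float = 0.7
) -> list[SelectedSite]:
    """Sites whose NEB posterior of belonging to an omega > 1 class passes the floor.

    Sites at or above ``high`` are starred (high-confidence candidates);
    sites below ``report_floor`` are excluded. Models without an omega > 1
    class return an empty list.
    """
    out = [
        SelectedSite(site, p, p >= high)
        for site, p in fit.pss
        if p >= report_floor
    ]
    out.sort(key=lambda s: (-s.posterior, s.site))
    return out


def fit_branch_model(
    aln: CodonAlignment,
    tree: dendropy.Tree,
    mode: str = "one_ratio",
    settings: FitSettings | None = None,
) -> tuple[BranchModelFit, LRTResult | None]:
    """One-ratio (single omega) or free-ratio (omega per branch) branch models.

    ``free_ratio`` also returns the LRT against the internally fitted
    one-ratio null (df = n_branches - 1). Branches whose fitted length hits
    the lower bound carry no information about their omega and are flagged
    unidentifiable.
    """
    if mode not in ("one_ratio", "free_ratio"):
        raise ModelError(f"unknown branch model mode {mode!r}")
    settings = settings or FitSettings()
    engine = PruningEngine(aln, tree)
    pi = codon_frequencies(aln, settings.freq_mode)
    nbr = engine.n_branches

    m0 = fit_site_model(aln, tree, "M0", settings)
    w0 = float(m0.model.omegas[0])
    t0 = np.array([m0.branch_lengths[b] for b in engine.branch_labels])
    one = BranchModelFit(
        mode="one_ratio",
        lnL=m0.lnL,
        kappa=m0.model.kappa,
        branch_lengths=dict(m0.branch_lengths),
        omega_by_branch={b: w0 for b in engine.branch_labels},
        n_params=nbr + 2,
        unidentifiable=[b for b, t in m0.branch_lengths.items() if t <= _T_UNIDENT],
    )
    if mode == "one_ratio":
        return one, None

    def neg(xf):
        t = np.exp(xf[:nbr])
        kappa = math.exp(xf[nbr])
        omegas = np.exp(xf[nbr + 1 :])
        eigs = {w: _SpectralQ(codon_rate_matrix(kappa, w, pi), pi) for w in set(omegas)}
        P = np.stack([eigs[w].propagators(np.array([tb]))[0] for w, tb in zip(omegas, t)])
        total, _ = engine.mixture_loglik(P[None, :], pi, np.array([0.0]))
        return -total

    x0 = np.concatenate(
        [
            np.log(np.clip(t0, _T_MIN, _T_MAX)),
            [math.log(m0.model.kappa)],
            np.full(nbr, math.log(max(w0, 1e-3))),
        ]
    )
    bounds = (
        [(math.log(_T_MIN), math.log(_T_MAX))] * nbr
        + [(math.log(_KAPPA_MIN), math.log(_KAPPA_MAX))]
        + [(math.log(_OMEGA_MIN), math.log(_OMEGA_MAX))] * nbr
    )
    xb, ll = _minimize(neg, x0, bounds, settings.maxiter_joint)
    t = np.exp(xb[:nbr])
    free = BranchModelFit(
        mode="free_ratio",
        lnL=ll,
        kappa=math.exp(xb[nbr]),
        branch_lengths=dict(zip(engine.branch_labels, map(float, t))),
        omega_by_branch=dict(zip(engine.branch_labels, map(float, np.exp(xb[nbr + 1 :])))),
        n_params=2 * nbr + 1,
        unidentifiable=[
            b for b, tb in zip(engine.branch_labels, t) if tb <= _T_UNIDENT
        ],
    )
    return free, likelihood_ratio_test(one, free)
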