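"""Codon model construction, pruning likelihood, fits, LRTs, site posteriors."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from seldiv._gencode import CODON_INDEX, SENSE_CODONS
from seldiv.codon_models import (
    CodonModel,
    FitSettings,
    ModelError,
    PruningEngine,
    SiteModelFit,
    codon_frequencies,
    codon_rate_matrix,
    discretize_beta,
    fit_branch_model,
    fit_site_model,
    likelihood_ratio_test,
    positively_selected_sites,
    site_log_likelihoods,
    transition_matrix,
)
from seldiv.phylo import read_newick
from seldiv.seqio import CodonAlignment, SequenceRecord
from seldiv.synthetic_data import balanced_tree, simulate_codon_alignment

EQ = np.full(61, 1 / 61)


def _model(kappa=2.0, omega=0.2, pi=EQ):
    return CodonModel(kappa=kappa, omega_classes=[(1.0, omega)], codon_freqs=pi,
                      freq_mode="equal")


def brute_force_loglik(aln, model, t_left, t_right):
    """Oracle: likelihood on ((a,b),(c,d)) by summing over both internal states.

    All five branches share one length pattern: leaves at t_left, the internal
    edge at t_right. Kept independent of the pruning engine on purpose.
    """
    pi = model.codon_freqs
    total = 0.0
    states = {
        r.id: [CODON_INDEX[r.seq[3 * c: 3 * c + 3]] for c in range(aln.n_codon_cols)]
        for r in aln.records
    }
    site_L = np.zeros(aln.n_codon_cols)
    for prop, omega in model.omega_classes:
        Q = codon_rate_matrix(model.kappa, omega, pi)
        Pl = expm(Q * t_left)
        Pr = expm(Q * t_right)
        for h in range(aln.n_codon_cols):
            a, b = states["t1"][h], states["t2"][h]
            c, d = states["t3"][h], states["t4"][h]
            Lh = 0.0
            for u in range(61):
                for v in range(61):
                    root = np.dot(pi * Pr[:, u], Pr[:, v])
                    Lh += root * Pl[u, a] * Pl[u, b] * Pl[v, c] * Pl[v, d]
            site_L[h] += prop * Lh
    return float(np.log(site_L).sum())


class TestRateMatrix:
    def test_rows_sum_to_zero(self):
        pi = codon_frequencies(
            CodonAlignment([SequenceRecord("a", "ATGGCTAAA"), SequenceRecord("b", "ATGGCCAAG")]),
            "F3x4",
        )
        Q = codon_rate_matrix(1.7, 0.4, pi)
        assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_neutral_equal_pi_rates_match(self):
        Q = codon_rate_matrix(1.0, 1.0, EQ)
        ttt, ttc, tta = CODON_INDEX["TTT"], CODON_INDEX["TTC"], CODON_INDEX["TTA"]
        assert Q[ttt, ttc] == pytest.approx(Q[ttt, tta])

    def test_omega_zero_kills_nonsynonymous_rates(self):
        Q = codon_rate_matrix(2.0, 0.0, EQ)
        ttt, tta = CODON_INDEX["TTT"], CODON_INDEX["TTA"]  # Phe -> Leu
        ttc = CODON_INDEX["TTC"]  # Phe -> Phe
        assert Q[ttt, tta] == 0.0
        assert Q[ttt, ttc] > 0.0

    def test_mean_rate_scaled_to_one(self):
        Q = codon_rate_matrix(2.5, 0.3, EQ)
        assert -(EQ * np.diag(Q)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_invalid_kappa_rejected(self):
        with pytest.raises(ModelError):
            codon_rate_matrix(0.0, 0.5, EQ)


class TestTransitionMatrix:
    def test_identity_at_zero(self):
        Q = codon_rate_matrix(2.0, 0.2, EQ)
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(61))

    def test_rows_stochastic(self):
        Q = codon_rate_matrix(2.0, 0.2, EQ)
        P = transition_matrix(Q, 0.7)
        assert np.allclose(P.sum(axis=1), 1.0, atol=1e-10)
        assert (P >= -1e-12).all()

    def test_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.full(61, 5.0))
        Q = codon_rate_matrix(1.8, 0.6, pi)
        P = transition_matrix(Q, 0.3)
        assert np.allclose(pi[:, None] * P, (pi[:, None] * P).T, atol=1e-10)

    def test_negative_time_rejected(self):
        with pytest.raises(ModelError):
            transition_matrix(codon_rate_matrix(2.0, 0.2, EQ), -0.1)


class TestSiteLogLikelihoods:
    def test_single_taxon_is_stationary_logprob(self):
        aln = CodonAlignment([SequenceRecord("A", "GCTAAA---")])
        tree = read_newick("A:0;")
        model = _model()
        ll, total = site_log_likelihoods(aln, tree, model)
        assert ll[0] == pytest.approx(math.log(1 / 61))
        assert ll[2] == 0.0
        assert total == pytest.approx(2 * math.log(1 / 61))

    def test_two_taxon_closed_form(self):
        aln = CodonAlignment(
            [SequenceRecord("A", "GCTAAA"), SequenceRecord("B", "GCCAAG")]
        )
        tree = read_newick("(A:0.2,B:0.3);")
        model = _model(kappa=2.0, omega=0.5)
        ll, _ = site_log_likelihoods(aln, tree, model)
        Q = codon_rate_matrix(2.0, 0.5, EQ)
        P1, P2 = expm(Q * 0.2), expm(Q * 0.3)
        for h, (a, b) in enumerate([("GCT", "GCC"), ("AAA", "AAG")]):
            direct = math.log(
                np.dot(EQ * P1[:, CODON_INDEX[a]], P2[:, CODON_INDEX[b]])
            )
            assert ll[h] == pytest.approx(direct, abs=1e-10)

    def test_pruning_matches_brute_force_enumeration(self):
        tree = balanced_tree(4, 0.3)
        model = CodonModel(
            kappa=2.0, omega_classes=[(0.7, 0.1), (0.3, 1.5)],
            codon_freqs=EQ, freq_mode="equal",
        )
        aln, _ = simulate_codon_alignment(tree, model, 20, seed=2)
        _, total = site_log_likelihoods(aln, tree, model)
        oracle = brute_force_loglik(aln, model, 0.3, 0.3)
        assert abs(total - oracle) < 1e-8

    def test_leaf_mismatch_lists_difference(self):
        aln = CodonAlignment(
            [SequenceRecord("A", "GCT"), SequenceRecord("X", "GCC")]
        )
        tree = read_newick("(A:0.1,B:0.1);")
        with pytest.raises(ModelError, match="B.*X"):
            site_log_likelihoods(aln, tree, _model())


@pytest.fixture(scope="module")
def m0_data():
    tree = balanced_tree(6, 0.2)
    aln, _ = simulate_codon_alignment(tree, _model(omega=0.2), 200, seed=7)
    return aln, tree


class TestFitSiteModel:

    def test_nesting_of_log_likelihoods(self, m0_data):
        aln, tree = m0_data
        settings = FitSettings()
        m0 = fit_site_model(aln, tree, "M0", settings)
        m3 = fit_site_model(aln, tree, "M3", settings, init_fit=m0)
        m7 = fit_site_model(aln, tree, "M7", settings, init_fit=m0)
        m8 = fit_site_model(aln, tree, "M8", settings, init_fit=m7)
        assert m3.lnL >= m0.lnL - 1e-4
        assert m8.lnL >= m7.lnL - 1e-4
        for fit in (m0, m3, m7, m8):
            assert np.allclose(fit.site_posteriors.sum(axis=1), 1.0, atol=1e-9)
            assert np.isfinite(fit.lnL)

    def test_parameter_counts(self, m0_data):
        aln, tree = m0_data
        settings = FitSettings()
        m0 = fit_site_model(aln, tree, "M0", settings)
        m3 = fit_site_model(aln, tree, "M3", settings, init_fit=m0)
        m7 = fit_site_model(aln, tree, "M7", settings, init_fit=m0)
        m8 = fit_site_model(aln, tree, "M8", settings, init_fit=m7)
        assert m3.n_params - m0.n_params == 4
        assert m8.n_params - m7.n_params == 2

    def test_identical_sequences_collapse_branch_lengths(self):
        row = "GCTAAAGTTCCG" * 5
        aln = CodonAlignment([SequenceRecord(t, row) for t in ("a", "b", "c")])
        tree = read_newick("(a:0.1,b:0.1,c:0.1);")
        fit = fit_site_model(aln, tree, "M0", FitSettings(freq_mode="equal"))
        assert all(t <= 1e-4 for t in fit.branch_lengths.values())
        expected = sum(
            math.log(1 / 61) for _ in range(aln.n_codon_cols)
        )
        assert fit.lnL == pytest.approx(expected, abs=0.01)


class TestLRT:
    def _fake(self, name, lnl, n_params):
        return SiteModelFit(
            model_name=name, lnL=lnl, model=_model(), branch_lengths={},
            n_params=n_params, site_posteriors=np.ones((1, 1)),
            site_loglik=np.zeros(1),
        )

    def test_two_delta_l_arithmetic(self):
        r = likelihood_ratio_test(self._fake("M7", -100.0, 10), self._fake("M8", -95.0, 12))
        assert r.two_delta_l == pytest.approx(10.0)
        assert r.df == 2

    def test_non_nested_pair_rejected(self):
        with pytest.raises(ModelError, match="nested"):
            likelihood_ratio_test(self._fake("M3", -10, 12), self._fake("M7", -9, 10))

    def test_alt_below_null_signals_optimizer_failure(self):
        with pytest.raises(ModelError, match="failure"):
            likelihood_ratio_test(self._fake("M7", -95.0, 10), self._fake("M8", -100.0, 12))


class TestPositivelySelectedSites:
    def _fit_with_posteriors(self, p_positive):
        post = np.column_stack([1 - np.asarray(p_positive), np.asarray(p_positive)])
        model = CodonModel(
            kappa=2.0, omega_classes=[(0.9, 0.1), (0.1, 2.5)],
            codon_freqs=EQ, freq_mode="equal",
        )
        return SiteModelFit(
            model_name="M8", lnL=-1.0, model=model, branch_lengths={},
            n_params=5, site_posteriors=post, site_loglik=np.zeros(len(p_positive)),
        )

    def test_starring_and_floor(self):
        fit = self._fit_with_posteriors([0.96, 0.65, 0.80])
        sel = positively_selected_sites(fit, high=0.95, report_floor=0.7)
        assert [(s.site, s.starred) for s in sel] == [(0, True), (2, False)]

    def test_monotone_in_report_floor(self):
        fit = self._fit_with_posteriors([0.96, 0.75, 0.71, 0.5])
        loose = {s.site for s in positively_selected_sites(fit, report_floor=0.7)}
        strict = {s.site for s in positively_selected_sites(fit, report_floor=0.9)}
        assert strict <= loose

    def test_model_without_selection_class_gives_empty_list(self):
        model = CodonModel(
            kappa=2.0, omega_classes=[(1.0, 0.3)], codon_freqs=EQ, freq_mode="equal"
        )
        fit = SiteModelFit(
            model_name="M7", lnL=-1.0, model=model, branch_lengths={},
            n_params=3, site_posteriors=np.ones((4, 1)), site_loglik=np.zeros(4),
        )
        assert positively_selected_sites(fit) == []


class TestBranchModels:
    def test_free_ratio_nests_one_ratio_and_flags_fast_branch(self):
        tree = balanced_tree(6, 0.2)
        aln, _ = simulate_codon_alignment(
            tree, _model(omega=0.2), 300, seed=33, branch_omegas={"t3": 3.0}
        )
        free, lrt = fit_branch_model(aln, tree, "free_ratio", FitSettings())
        one, _ = fit_branch_model(aln, tree, "one_ratio", FitSettings())
        assert free.lnL >= one.lnL - 1e-4
        assert lrt.df == len(free.omega_by_branch) - 1
        assert "t3" in free.flagged_branches
        assert free.omega_by_branch["t3"] > 1.0

    def test_identical_sequences_marked_unidentifiable(self):
        row = "GCTAAAGTTCCGATG" * 4
        aln = CodonAlignment([SequenceRecord(t, row) for t in ("a", "b", "c")])
        tree = read_newick("(a:0.1,b:0.1,c:0.1);")
        one, _ = fit_branch_model(aln, tree, "one_ratio", FitSettings(freq_mode="equal"))
        assert set(one.unidentifiable) == {"a", "b", "c"}
        assert one.flagged_branches == []


class TestBetaDiscretization:
    def test_class_medians_bracket_the_mean(self):
        om = discretize_beta(2.0, 2.0, 10)
        assert om.shape == (10,)
        assert np.all(np.diff(om) > 0)
        assert om.mean() == pytest.approx(0.5, abs=0.01)
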