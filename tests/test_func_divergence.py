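"""Fitch change counts, Type-I mixture estimation, Type-II radical shifts."""

import math

import numpy as np
import pytest
from scipy import stats

from seldiv.func_divergence import (
    CHARGE,
    ChangeCountTable,
    PropertyPartition,
    ancestral_states,
    change_count_table,
    fit_type1,
    fit_type2,
    fitch_site_changes,
    type1_caas,
    _log_nb,
)
from seldiv.phylo import read_newick
from seldiv.seqio import GroupAssignment, ProteinAlignment, SequenceRecord
from seldiv.synthetic_data import simulate_rate_shift_counts


def _aln(cols: list[str], ids=("a1", "a2", "b1", "b2")) -> ProteinAlignment:
    rows = ["".join(col[i] for col in cols) for i in range(len(ids))]
    return ProteinAlignment([SequenceRecord(i, r) for i, r in zip(ids, rows)])


class TestFitchChanges:
    def test_constant_column_needs_no_changes(self, quartet_tree):
        assert fitch_site_changes(_aln(["AAAA"]), quartet_tree)[0] == 0

    def test_clade_split_column_needs_one_change(self, quartet_tree):
        assert fitch_site_changes(_aln(["AABB"]), quartet_tree)[0] == 1

    def test_alternating_column_needs_two_changes(self, quartet_tree):
        assert fitch_site_changes(_aln(["ABAB"]), quartet_tree)[0] == 2

    def test_missing_data_excluded(self, quartet_tree):
        assert fitch_site_changes(_aln(["A-A-"]), quartet_tree)[0] == 0

    def test_leaf_mismatch_raises(self, quartet_tree):
        aln = _aln(["AAAA"], ids=("a1", "a2", "b1", "zz"))
        with pytest.raises(ValueError, match="b2"):
            fitch_site_changes(aln, quartet_tree)


class TestAncestralStates:
    def test_constant_column(self, quartet_tree):
        assert ancestral_states(_aln(["AAAA"]), quartet_tree)[0] == "A"

    def test_tie_broken_by_consensus_then_alphabet(self):
        cherry = read_newick("(a1:1,a2:1);")
        aln = ProteinAlignment([SequenceRecord("a1", "AB"), SequenceRecord("a2", "BB")])
        states = ancestral_states(aln, cherry)
        assert states[0] == "A"  # 1-1 tie -> alphabetical
        assert states[1] == "B"

    def test_consensus_wins_over_alphabet(self, quartet_tree):
        states = ancestral_states(_aln(["CCCA"]), quartet_tree)
        assert states[0] == "C"

    def test_all_gap_column_is_missing(self, quartet_tree):
        assert ancestral_states(_aln(["----"]), quartet_tree)[0] is None


class TestTypeI:
    def test_recovery_of_generating_theta(self):
        counts, _ = simulate_rate_shift_counts(500, 0.5, 0.5, 2.0, 2.0, seed=9)
        r = fit_type1(counts)
        assert 0.35 <= r.theta1 <= 0.65
        assert r.lrt > 3.84

    def test_null_data_rarely_rejects(self):
        lrts = []
        for s in range(20):
            counts, _ = simulate_rate_shift_counts(500, 0.0, 0.5, 1.5, 1.5, seed=300 + s)
            lrts.append(fit_type1(counts).lrt)
        assert sum(l < 3.84 for l in lrts) >= 18

    def test_qk_mean_tracks_theta(self):
        counts, _ = simulate_rate_shift_counts(500, 0.3, 0.5, 1.5, 1.5, seed=5)
        r = fit_type1(counts)
        assert np.all((r.qk >= 0) & (r.qk <= 1))
        assert abs(r.qk.mean() - r.theta1) < 0.05

    def test_invariant_to_cluster_swap(self):
        counts, _ = simulate_rate_shift_counts(300, 0.4, 0.8, 1.0, 2.0, seed=13)
        swapped = ChangeCountTable(counts.counts[:, ::-1], counts.labels[::-1])
        r1, r2 = fit_type1(counts), fit_type1(swapped)
        assert r1.theta1 == pytest.approx(r2.theta1, abs=1e-3)
        assert r1.d1 == pytest.approx(r2.d2, rel=1e-2)

    def test_all_zero_cluster_rejected(self):
        table = ChangeCountTable(
            np.column_stack([np.zeros(30), np.ones(30)]), ("a", "b")
        )
        with pytest.raises(ValueError, match="zero changes"):
            fit_type1(table)

    def test_few_sites_warns(self):
        counts, _ = simulate_rate_shift_counts(10, 0.3, 0.5, 1.5, 1.5, seed=1)
        with pytest.warns(UserWarning, match="unstable"):
            fit_type1(counts)

    def test_nb_marginal_approaches_poisson(self):
        x = np.arange(0, 30, dtype=float)
        nb = np.exp(_log_nb(x, 1e6, 2.5))
        pois = stats.poisson.pmf(x, 2.5)
        assert np.abs(nb - pois).max() < 1e-6

    def test_counts_from_alignment_and_tree(self, quartet_tree, two_cluster_groups):
        aln = _aln(["AAAA", "ABAA", "AABB"])
        table = change_count_table(aln, quartet_tree, two_cluster_groups)
        assert table.labels == ("monocot", "dicot")
        assert table.counts.tolist() == [[0, 0], [1, 0], [0, 0]]


class TestCAAS:
    def _result(self, qk):
        return type("StubResult", (), {"qk": np.asarray(qk)})()

    def test_threshold_selection_sorted_by_qk(self):
        hits = type1_caas(self._result([0.95, 0.5, 0.91]), 0.9)
        assert hits == [(0, 0.95), (2, 0.91)]

    def test_threshold_one_empty(self):
        assert type1_caas(self._result([0.95, 0.99]), 1.0) == []

    def test_lowering_threshold_never_removes_sites(self):
        r = self._result([0.95, 0.85, 0.5, 0.92])
        high = {k for k, _ in type1_caas(r, 0.9)}
        low = {k for k, _ in type1_caas(r, 0.8)}
        assert high <= low


class TestTypeII:
    def _setup(self, cols):
        aln = _aln(cols)
        tree = read_newick("((a1:1,a2:1):1,(b1:1,b2:1):1);")
        groups = GroupAssignment(
            {"a1": "mono", "a2": "mono", "b1": "dico", "b2": "dico"}
        )
        return aln, tree, groups

    def _bg_columns(self):
        # non-applicable columns fixing the background p_r0 = 1/5: cluster a
        # is polymorphic with one radical (K/D) and four conserved (A/G)
        # consensus-vs-other events; each string is a column over (a1,a2,b1,b2)
        return ["KDAA", "AGAA", "AGAA", "AGAA", "AGAA"]

    def test_all_radical_gives_theta_one_exactly(self):
        # two applicable differing sites, both radical (K vs D, R vs E)
        aln, tree, groups = self._setup(["KKDD", "RREE"] + self._bg_columns())
        r = fit_type2(aln, tree, groups, CHARGE)
        assert r.p_r0 == pytest.approx(0.2)
        assert r.theta2 == 1.0

    def test_pi_r_equal_background_gives_theta_zero_exactly(self):
        # five applicable differing sites: one radical, four conserved
        diff = ["KKDD", "AAGG", "AAGG", "AAGG", "AAGG"]
        aln, tree, groups = self._setup(diff + self._bg_columns())
        r = fit_type2(aln, tree, groups, CHARGE)
        assert r.p_r0 == pytest.approx(0.2)
        assert r.pi_r == pytest.approx(0.2)
        assert r.theta2 == 0.0

    def test_negative_theta_when_radical_rarer_than_background(self):
        diff = ["AAGG"] * 5  # all conserved differences
        aln, tree, groups = self._setup(diff + self._bg_columns())
        r = fit_type2(aln, tree, groups, CHARGE)
        assert r.theta2 < 0

    def test_no_differing_sites_is_undefined(self):
        aln, tree, groups = self._setup(["AAAA", "KKKK"] + self._bg_columns())
        r = fit_type2(aln, tree, groups, CHARGE)
        assert not r.defined
        assert math.isnan(r.theta2)

    def test_invariant_to_group_relabeling(self):
        cols = ["KKDD", "AAGG", "STAA"] + self._bg_columns()
        aln, tree, groups = self._setup(cols)
        relabeled = PropertyPartition(
            "charge-permuted",
            (frozenset("DE"), frozenset("KRH"), frozenset("ACFGILMNPQSTVWY")),
        )
        assert fit_type2(aln, tree, groups, CHARGE).theta2 == pytest.approx(
            fit_type2(aln, tree, groups, relabeled).theta2
        )

    def test_site_classification_labels(self):
        cols = ["AAAA", "KKDD", "AAGG"] + self._bg_columns()
        aln, tree, groups = self._setup(cols)
        r = fit_type2(aln, tree, groups, CHARGE)
        assert r.site_class[:3] == [
            "no_difference", "radical_difference", "conserved_difference",
        ]
        assert set(r.site_class[3:]) == {"not_applicable"}


class TestPropertyPartition:
    def test_partitions_cover_and_disjoint(self):
        # constructor validates; charge partition classifies K->D as radical
        assert CHARGE.is_radical("K", "D")
        assert not CHARGE.is_radical("A", "G")

    def test_incomplete_partition_rejected(self):
        with pytest.raises(ValueError, match="cover"):
            PropertyPartition("bad", (frozenset("KR"),))
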