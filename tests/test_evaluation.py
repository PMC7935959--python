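"""Multifunctionality scores, Mann-Whitney AUCs, deltas and version updates."""

import numpy as np
import pandas as pd
import pytest
from fractions import Fraction

import consica as ci
from consica.evaluation import (
    evaluate_collection,
    improvement_delta,
    member_nonmember_auc,
    multifunctionality,
    multifunctionality_association,
    pan_collection_multifunctionality,
    version_update_eval,
)
from consica.io import GeneSetCollection, PredictionScoreTable, ValidationError

from oracles import auc_pair_counting


def _universe(n):
    return [f"G{i + 1}" for i in range(n)]


class TestMultifunctionality:
    def test_unannotated_gene_scores_zero(self, toy_collection):
        mf = multifunctionality(toy_collection).to_series()
        assert mf.loc["G100"] == 0.0

    def test_two_set_toy_value(self, toy_collection):
        # G1 in a 10-set and a 20-set over a 100-gene universe
        mf = multifunctionality(toy_collection).to_series()
        expected = Fraction(1, 10 * 90) + Fraction(1, 20 * 80)
        assert mf.loc["G1"] == pytest.approx(float(expected), rel=1e-15)
        assert mf.loc["G1"] == pytest.approx(0.00173611111111, abs=1e-12)

    def test_single_common_set_symmetry(self):
        u = _universe(100)
        coll = GeneSetCollection("c", frozenset(u), {"S": tuple(u[:50])}, (10, 500))
        mf = multifunctionality(coll).to_series()
        members = mf.loc[[f"G{i + 1}" for i in range(50)]]
        assert (members == 1 / 2500).all()
        assert (mf.loc[[f"G{i + 1}" for i in range(50, 100)]] == 0).all()

    def test_whole_universe_set_rejected(self):
        u = _universe(20)
        coll = GeneSetCollection("c", frozenset(u), {"ALL": tuple(u)}, (1, 20))
        with pytest.raises(ValidationError, match="ALL"):
            multifunctionality(coll)

    def test_invariant_to_set_and_gene_order(self, toy_collection):
        mf1 = multifunctionality(toy_collection).to_series()
        reordered = GeneSetCollection(
            "toy2", toy_collection.universe,
            dict(reversed(list(toy_collection.sets.items()))),
            toy_collection.size_bounds,
        )
        mf2 = multifunctionality(reordered).to_series()
        pd.testing.assert_series_equal(mf1, mf2, check_names=False)


class TestPanCollection:
    def test_single_collection_identity(self, toy_collection):
        single = pan_collection_multifunctionality([toy_collection])
        np.testing.assert_allclose(
            single.scores, multifunctionality(toy_collection).scores
        )

    def test_duplication_doubles_scores(self, toy_collection):
        double = pan_collection_multifunctionality([toy_collection, toy_collection])
        np.testing.assert_allclose(
            double.scores, 2 * multifunctionality(toy_collection).scores
        )

    def test_disjoint_collections_sum(self):
        u = _universe(60)
        c1 = GeneSetCollection("a", frozenset(u), {"A": tuple(u[:12])}, (10, 500))
        c2 = GeneSetCollection("b", frozenset(u), {"B": tuple(u[30:45])}, (10, 500))
        pan = pan_collection_multifunctionality([c1, c2]).to_series()
        assert pan.loc["G1"] == pytest.approx(1 / (12 * 48), rel=1e-14)
        assert pan.loc["G31"] == pytest.approx(1 / (15 * 45), rel=1e-14)
        assert pan.loc["G60"] == 0.0

    def test_inconsistent_universe_rejected(self, toy_collection):
        other = GeneSetCollection(
            "o", frozenset(_universe(10)), {"S": tuple(_universe(10))[:10]}, (1, 10)
        )
        with pytest.raises(ValidationError):
            pan_collection_multifunctionality([toy_collection, other])


class TestAuc:
    def test_perfect_separation(self):
        auc, _ = member_nonmember_auc([5, 6, 7], [1, 2, 3])
        assert auc == 1.0

    def test_identical_groups(self):
        auc, _ = member_nonmember_auc([1, 2, 3], [1, 2, 3])
        assert auc == 0.5

    def test_ties_match_exhaustive_pair_counting(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        auc, _ = member_nonmember_auc(a, b)
        assert auc == pytest.approx(auc_pair_counting(a, b), abs=1e-12)

    def test_random_groups_match_pair_counting(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            a = rng.integers(0, 5, size=rng.integers(2, 15)).astype(float)
            b = rng.integers(0, 5, size=rng.integers(2, 15)).astype(float)
            auc, _ = member_nonmember_auc(a, b)
            assert auc == pytest.approx(auc_pair_counting(a, b), abs=1e-12)

    def test_complementarity(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=9), rng.normal(size=7)
        auc_ab, _ = member_nonmember_auc(a, b)
        auc_ba, _ = member_nonmember_auc(b, a)
        assert auc_ab + auc_ba == pytest.approx(1.0, abs=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            member_nonmember_auc([], [1.0])


def _table(scores, sets, genes=None):
    scores = np.asarray(scores, dtype=float)
    genes = genes or [f"G{i + 1}" for i in range(scores.shape[0])]
    return PredictionScoreTable(genes, sets, scores)


class TestEvaluateCollection:
    def _coll(self):
        u = _universe(6)
        return GeneSetCollection(
            "c", frozenset(u),
            {"A": ("G1", "G2"), "B": ("G3", "G4")}, (2, 10),
        )

    def test_separated_scores_give_ordered_medians(self):
        t = _table([[9, 1], [8, 2], [1, 9], [2, 8], [0, 0], [0.5, 0.5]],
                   ["A", "B"], _universe(6))
        summary = evaluate_collection(t, self._coll())
        assert (summary.per_set["median_member"]
                > summary.per_set["median_nonmember"]).all()

    def test_constant_scores_give_flat_medians_and_half_auc(self):
        t = _table(np.full((6, 2), 3.0), ["A", "B"], _universe(6))
        summary = evaluate_collection(t, self._coll())
        assert (summary.per_set["median_member"] == 3.0).all()
        assert summary.auc == 0.5

    def test_toy_medians_match_hand_computation(self):
        t = _table([[4, 0], [6, 0], [0, 1], [0, 3], [1, 2], [-1, -2]],
                   ["A", "B"], _universe(6))
        summary = evaluate_collection(t, self._coll())
        assert summary.per_set.loc["A", "median_member"] == 5.0
        assert summary.per_set.loc["B", "median_member"] == 2.0
        # nonmembers are G5, G6
        assert summary.per_set.loc["A", "median_nonmember"] == 0.0
        assert summary.per_set.loc["B", "median_nonmember"] == 0.0

    def test_no_unannotated_genes_rejected(self):
        u = _universe(4)
        coll = GeneSetCollection("c", frozenset(u),
                                 {"A": ("G1", "G2"), "B": ("G3", "G4")}, (2, 10))
        t = _table(np.zeros((4, 2)), ["A", "B"], u)
        with pytest.raises(ValidationError):
            evaluate_collection(t, coll)


class TestImprovementDelta:
    def _setup(self):
        u = _universe(6)
        coll = GeneSetCollection("c", frozenset(u),
                                 {"A": ("G1", "G2"), "B": ("G3", "G4")}, (2, 10))
        rng = np.random.default_rng(0)
        ica = _table(rng.normal(size=(6, 2)), ["A", "B"], u)
        return coll, ica

    def test_identical_tables_all_tied(self):
        coll, ica = self._setup()
        same = _table(ica.scores.copy(), ica.set_names, ica.gene_ids)
        summary = improvement_delta(ica, same, coll)
        assert (summary.per_set["class"] == "tied").all()

    def test_uniform_shift_all_ica_improved(self):
        coll, ica = self._setup()
        pca = _table(ica.scores - 1.0, ica.set_names, ica.gene_ids)
        summary = improvement_delta(ica, pca, coll)
        assert (summary.per_set["class"] == "ica-improved").all()
        np.testing.assert_allclose(summary.per_set["delta"], 1.0)

    def test_deltas_match_hand_medians(self):
        coll, _ = self._setup()
        ica = _table([[4, 0], [6, 0], [0, 1], [0, 3], [0, 0], [0, 0]],
                     ["A", "B"], _universe(6))
        pca = _table([[1, 0], [3, 0], [0, 5], [0, 7], [0, 0], [0, 0]],
                     ["A", "B"], _universe(6))
        summary = improvement_delta(ica, pca, coll)
        assert summary.per_set.loc["A", "delta"] == 5.0 - 2.0
        assert summary.per_set.loc["B", "delta"] == 2.0 - 6.0
        assert summary.per_set.loc["A", "class"] == "ica-improved"
        assert summary.per_set.loc["B", "class"] == "pca-improved"


class TestVersionUpdate:
    def _colls(self, gained):
        u = _universe(12)
        old = GeneSetCollection("old", frozenset(u),
                                {"S": ("G1", "G2", "G3")}, (2, 12))
        new_members = ("G1", "G2", "G3") + tuple(gained)
        new = GeneSetCollection("new", frozenset(u), {"S": new_members}, (2, 12))
        return old, new

    def test_identical_versions_give_empty_result(self):
        old, _ = self._colls(())
        t = _table(np.zeros((12, 1)), ["S"], _universe(12))
        result = version_update_eval(t, t, old, old)
        assert result.empty

    def test_gained_genes_identified_exactly(self):
        old, new = self._colls(("G9", "G10"))
        t = _table(np.arange(12.0)[:, None], ["S"], _universe(12))
        result = version_update_eval(t, t, old, new)
        assert tuple(result.loc["S", "updated_members"]) == ("G9", "G10")
        # G9 scores 8.0, G10 scores 9.0
        assert result.loc["S", "median_old_barcode"] == pytest.approx(8.5)

    def test_fuller_barcode_improves_heldout_scores(self):
        """Completing the membership raises held-out members' medians in
        nearly all seeded replicates (desk-scale analog of the version-update
        evaluation)."""
        df = ci.version_update_experiment(
            n_replicates=4, seed=11, n_genes=150, n_samples=300, k=3, n_perm=150
        )
        assert df["new_wins"].sum() >= 3


class TestMultifunctionalityAssociation:
    def test_structure_free_association_is_low(self):
        # enough genes that the V-statistic's finite-sample floor (~n^-1/2)
        # sits below the 0.1 bound
        from consica.decomposition import MixingMatrix

        rng = np.random.default_rng(7)
        n = 400
        W = rng.normal(size=(n, 5))
        MM = MixingMatrix([f"G{i + 1}" for i in range(n)],
                          [f"TC{j + 1}" for j in range(5)], W, np.ones(5))
        coll = ci.generate_random_collection(MM.gene_ids, n_sets=6,
                                             size_range=(10, 20), seed=5)
        table = ci.score_all(MM, coll, method="ica", n_perm=200, seed=1)
        assoc = multifunctionality_association(table, multifunctionality(coll))
        assert ((assoc >= 0) & (assoc <= 1)).all()
        assert assoc.median() < 0.1
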