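"""Barcodes, distance correlation, permutation nulls and prediction scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import consica as ci
from consica._dcor import distance_correlation
from consica.decomposition import MixingMatrix
from consica.gba import (
    _kde_tail_log_p,
    build_null,
    gene_barcode,
    prediction_score,
    set_barcode,
    silverman_bandwidth,
)
from consica.io import GeneSetCollection, ValidationError
from consica.simulate import planted_collection

from oracles import dcor_bruteforce, kde_tail_bruteforce, welch_t_bruteforce


def _mm(weights):
    weights = np.asarray(weights, dtype=float)
    return MixingMatrix(
        gene_ids=[f"G{i + 1}" for i in range(weights.shape[0])],
        component_ids=[f"TC{j + 1}" for j in range(weights.shape[1])],
        weights=weights,
        credibility=np.ones(weights.shape[1]),
    )


class TestDistanceCorrelation:
    def test_linear_dependence_gives_one(self):
        x = np.array([0.3, 1.2, 2.2, 5.0, -1.0])
        assert distance_correlation(x, 2 * x + 1) == pytest.approx(1.0, abs=1e-12)

    def test_constant_input_gives_zero(self):
        assert distance_correlation(np.ones(6), np.arange(6.0)) == 0.0

    def test_small_example_matches_bruteforce(self):
        x, y = [1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 2.0, 5.0]
        assert distance_correlation(x, y) == pytest.approx(
            dcor_bruteforce(x, y), abs=1e-12
        )

    def test_agrees_with_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            n = int(rng.integers(3, 61))
            x = rng.normal(size=n)
            y = rng.normal(size=n) + rng.uniform(-1, 1) * x
            assert abs(distance_correlation(x, y) - dcor_bruteforce(x, y)) <= 1e-12

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            distance_correlation([1, 2, 3], [1, 2])

    @settings(derandomize=True, max_examples=25)
    @given(st.lists(st.floats(-50, 50), min_size=3, max_size=20),
           st.integers(0, 2**31 - 1))
    def test_in_unit_interval_and_symmetric(self, xs, seed):
        rng = np.random.default_rng(seed)
        x = np.asarray(xs)
        y = rng.normal(size=len(xs))
        d = distance_correlation(x, y)
        assert 0.0 <= d <= 1.0 + 1e-12
        assert d == pytest.approx(distance_correlation(y, x), abs=1e-12)


class TestSetBarcode:
    def test_single_member_equals_gene_row(self):
        MM = _mm([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        bc = set_barcode(MM, ["G2"], method="ica_mean")
        np.testing.assert_array_equal(bc.values, [3.0, 4.0])

    def test_mean_of_two_rows(self):
        MM = _mm([[1.0, 3.0], [3.0, 1.0], [0.0, 0.0]])
        bc = set_barcode(MM, ["G1", "G2"], method="ica_mean")
        np.testing.assert_array_equal(bc.values, [2.0, 2.0])

    def test_welch_t_matches_hand_formula(self, planted_fixture):
        X, _ = planted_fixture
        basis = ci.whiten(X)
        MM = _mm(np.zeros((len(basis.gene_ids), 2)))
        MM.gene_ids = list(basis.gene_ids)
        members = basis.gene_ids[:2]
        bc = set_barcode(MM, members, method="pca_welch_t", basis=basis)
        expected = welch_t_bruteforce(basis.loadings[:2], basis.loadings[2:])
        np.testing.assert_allclose(bc.values, expected, atol=1e-10)

    def test_unknown_gene_rejected(self):
        MM = _mm([[1.0], [2.0]])
        with pytest.raises(ValidationError, match="unknown"):
            set_barcode(MM, ["NOPE"], method="ica_mean")


class TestBuildNull:
    def test_samples_within_statistic_range(self, random_mixing):
        bc = gene_barcode(random_mixing, "G1")
        null = build_null(bc, random_mixing, set_size=10, n_perm=200, seed=0)
        assert (null.samples >= 0).all() and (null.samples <= 1).all()

    def test_exhaustive_set_size_degenerate_but_defined(self, random_mixing):
        bc = gene_barcode(random_mixing, "G3")
        n = len(random_mixing.gene_ids)
        null = build_null(bc, random_mixing, set_size=n, n_perm=150, seed=0)
        assert np.ptp(null.samples) < 1e-12
        assert null.kde_bandwidth > 0
        z = prediction_score(float(null.samples[0]), null)
        assert np.isfinite(z)

    def test_small_n_perm_rejected(self, random_mixing):
        bc = gene_barcode(random_mixing, "G1")
        with pytest.raises(ValidationError):
            build_null(bc, random_mixing, set_size=10, n_perm=50, seed=0)

    def test_null_reproduces_under_independent_resimulation(self, random_mixing):
        """Two independently seeded nulls for the same (gene, size) are
        draws from the same distribution (two-sample KS)."""
        bc = gene_barcode(random_mixing, "G5")
        a = build_null(bc, random_mixing, set_size=12, n_perm=1000, seed=1,
                       gene_id="G5")
        b = build_null(bc, random_mixing, set_size=12, n_perm=1000, seed=2,
                       gene_id="G5")
        assert stats.ks_2samp(a.samples, b.samples).pvalue > 0.01


class TestPredictionScore:
    def test_z_near_zero_at_null_median(self, random_mixing):
        bc = gene_barcode(random_mixing, "G2")
        null = build_null(bc, random_mixing, set_size=10, n_perm=1000, seed=0)
        z = prediction_score(float(np.median(null.samples)), null)
        assert abs(z) < 0.05

    def test_observed_below_all_samples_is_negative(self, random_mixing):
        bc = gene_barcode(random_mixing, "G2")
        null = build_null(bc, random_mixing, set_size=10, n_perm=200, seed=0)
        assert prediction_score(float(null.samples.min()) - 0.5, null) < 0

    def test_tail_probability_matches_mixture_oracle(self):
        from consica.gba import NullDistribution

        samples = np.array([0.1, 0.2, 0.3])
        h = silverman_bandwidth(samples)
        log_p = _kde_tail_log_p(0.25, samples, h)
        assert np.exp(log_p) == pytest.approx(
            kde_tail_bruteforce(0.25, samples, h), abs=1e-10
        )
        null = NullDistribution(samples, h, 3, 2, 0)
        z = prediction_score(0.25, null)
        assert z == pytest.approx(-stats.norm.ppf(kde_tail_bruteforce(0.25, samples, h)),
                                  abs=1e-8)

    def test_strictly_monotone_in_observed(self, random_mixing):
        bc = gene_barcode(random_mixing, "G4")
        null = build_null(bc, random_mixing, set_size=15, n_perm=300, seed=0)
        grid = np.linspace(-0.2, 1.2, 60)
        zs = [prediction_score(o, null) for o in grid]
        assert np.all(np.diff(zs) > 0)

    def test_finite_far_into_the_tail(self, random_mixing):
        bc = gene_barcode(random_mixing, "G4")
        null = build_null(bc, random_mixing, set_size=15, n_perm=300, seed=0)
        assert np.isfinite(prediction_score(50.0, null))
        assert np.isfinite(prediction_score(-50.0, null))


class TestScoreAll:
    def test_planted_members_outrank_nonmembers(self, decomposed, planted_sets):
        _, _, MM, _ = decomposed
        table = ci.score_all(MM, planted_sets, method="ica", n_perm=300, seed=5)
        mask = planted_sets.member_mask(table.gene_ids).to_numpy()
        member = table.scores[mask]
        nonmember = table.scores[~mask]
        assert np.median(member) > np.percentile(nonmember, 95)

    def test_pca_parametric_zero_correlation_gives_zero(self):
        from consica.gba import _parametric_pearson_z

        assert _parametric_pearson_z(0.0, 20) == pytest.approx(0.0, abs=1e-12)

    def test_row_reordering_invariance(self, random_mixing):
        """Permuting the mixing-matrix rows (genes keep their identifiers)
        leaves every (gene, set) score identical."""
        rng = np.random.default_rng(0)
        universe = list(random_mixing.gene_ids)
        coll = ci.generate_random_collection(universe, n_sets=3,
                                             size_range=(8, 12), seed=1)
        t1 = ci.score_all(random_mixing, coll, method="ica", n_perm=150, seed=3)
        perm = rng.permutation(len(universe))
        MM2 = MixingMatrix(
            gene_ids=[universe[p] for p in perm],
            component_ids=list(random_mixing.component_ids),
            weights=random_mixing.weights[perm],
            credibility=random_mixing.credibility,
        )
        t2 = ci.score_all(MM2, coll, method="ica", n_perm=150, seed=3)
        df1, df2 = t1.to_frame(), t2.to_frame()
        np.testing.assert_array_equal(df2.loc[df1.index].to_numpy(), df1.to_numpy())

    def test_cached_nulls_match_per_pair_scoring(self, random_mixing):
        coll = ci.generate_random_collection(
            random_mixing.gene_ids, n_sets=2, size_range=(10, 10), seed=2
        )
        table = ci.score_all(random_mixing, coll, method="ica", n_perm=200, seed=4)
        gi = 7
        gid = random_mixing.gene_ids[gi]
        bc = gene_barcode(random_mixing, gid)
        null = build_null(bc, random_mixing, set_size=10, n_perm=200, seed=4,
                          gene_id=gid)
        for j, name in enumerate(coll.set_names):
            sb = set_barcode(random_mixing, coll.sets[name], method="ica_mean")
            obs = distance_correlation(bc.values, sb.values)
            assert table.scores[gi, j] == pytest.approx(
                prediction_score(obs, null), abs=1e-12
            )

    def test_global_sign_flip_and_component_permutation_invariance(
        self, decomposed, planted_sets
    ):
        """dcor treats a barcode as unordered scalar observations, so scores
        are invariant to negating all components at once and to permuting
        component order (a single component's flip does change the statistic)."""
        _, _, MM, _ = decomposed
        rng = np.random.default_rng(8)
        perm = rng.permutation(MM.n_components)
        transformed = MixingMatrix(
            gene_ids=list(MM.gene_ids),
            component_ids=[MM.component_ids[j] for j in perm],
            weights=-MM.weights[:, perm],
            credibility=MM.credibility[perm],
        )
        t1 = ci.score_all(MM, planted_sets, method="ica", n_perm=150, seed=6)
        t2 = ci.score_all(transformed, planted_sets, method="ica", n_perm=150, seed=6)
        np.testing.assert_allclose(t1.scores, t2.scores, atol=1e-9)

    def test_empty_collection_rejected(self, random_mixing):
        empty = GeneSetCollection("e", frozenset(random_mixing.gene_ids), {}, (1, 500))
        with pytest.raises(ValidationError, match="empty"):
            ci.score_all(random_mixing, empty, method="ica", n_perm=150, seed=0)
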