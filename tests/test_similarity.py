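import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hcascreen import (
    AnalysisError,
    FeatureSchema,
    ProfileTable,
    attribute_channels,
    dynamic_range,
    feature_significance,
    mahalanobis_profile,
    organelle_sim_idx,
    pairwise_sim_idx,
    screen_similarity,
    sim_idx,
    simulate_screen,
)
from hcascreen.scenarios import null_screen


def oracle_ttest_p(x, y, equal_var=True):
    """Closed-form two-sided two-sample t-test, independent of the package."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    diff = x.mean() - y.mean()
    if equal_var:
        sp2 = ((nx - 1) * vx + (ny - 1) * vy) / (nx + ny - 2)
        se = np.sqrt(sp2 * (1 / nx + 1 / ny))
        df = nx + ny - 2
    else:
        se = np.sqrt(vx / nx + vy / ny)
        df = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
    t = diff / se
    return 2 * stats.t.sf(abs(t), df)


def _schema(n):
    return FeatureSchema(feature_names=tuple(f"f{i}" for i in range(n)))


class TestFeatureSignificance:
    def test_identical_tables_yield_no_significance(self, make_table):
        a = make_table("a", seed=1)
        b = ProfileTable("b", a.schema, a.values.copy())
        sig = feature_significance(a, b)
        assert not sig.h.any()
        # identical samples give t = 0 exactly, p = 1 on non-degenerate features
        np.testing.assert_allclose(sig.p_values[sig.countable], 1.0)

    def test_strong_shift_is_detected(self):
        schema = _schema(1)
        a = ProfileTable("a", schema, np.array([[0.0], [0.0], [0.0], [0.0], [0.0]]))
        b = ProfileTable("b", schema, np.array([[5.0], [5.1], [4.9], [5.2], [4.8]]))
        sig = feature_significance(a, b, alpha=0.05)
        assert sig.h[0] == 1
        assert sig.p_values[0] < 1e-6

    def test_constant_equal_feature_is_degenerate(self):
        schema = _schema(2)
        a = ProfileTable("a", schema, np.column_stack([np.ones(5), np.arange(5.0)]))
        b = ProfileTable("b", schema, np.column_stack([np.ones(4), np.arange(4.0)]))
        sig = feature_significance(a, b)
        assert sig.degenerate[0] and not sig.degenerate[1]
        assert sig.h[0] == 0
        assert not sig.countable[0]

    def test_constant_unequal_feature_is_certainly_different(self):
        schema = _schema(1)
        a = ProfileTable("a", schema, np.zeros((4, 1)))
        b = ProfileTable("b", schema, np.ones((4, 1)))
        sig = feature_significance(a, b)
        assert sig.h[0] == 1

    def test_too_few_cells_marks_feature_unusable(self):
        schema = _schema(2)
        a_vals = np.array([[1.0, 0.5], [np.nan, 0.7], [np.nan, 0.9]])
        b_vals = np.array([[0.0, 5.0], [0.5, 5.2], [0.2, 5.4]])
        sig = feature_significance(
            ProfileTable("a", schema, a_vals), ProfileTable("b", schema, b_vals)
        )
        assert not sig.usable[0] and sig.usable[1]
        assert sig.h[0] == 0

    @pytest.mark.parametrize("variance_mode", ["pooled", "welch"])
    def test_matches_closed_form_oracle(self, variance_mode):
        """Random 20-feature instances agree with the hand-written t-test."""
        rng = np.random.default_rng(42)
        schema = _schema(20)
        a = ProfileTable("a", schema, rng.normal(0, 1, size=(15, 20)))
        b = ProfileTable("b", schema, rng.normal(0.3, 1.7, size=(12, 20)))
        sig = feature_significance(a, b, variance_mode=variance_mode)
        for f in range(20):
            expected = oracle_ttest_p(
                a.values[:, f], b.values[:, f], equal_var=(variance_mode == "pooled")
            )
            assert sig.p_values[f] == pytest.approx(expected, abs=1e-12)


class TestSimIdx:
    def _sig(self, h, n=None):
        n = n or len(h)
        schema = _schema(n)
        h = np.asarray(h, dtype=np.int8)
        from hcascreen.similarity import SignificanceVector

        return SignificanceVector(
            schema=schema,
            h=h,
            p_values=np.where(h == 1, 0.01, 0.9),
            alpha=0.05,
            n_a=10,
            n_b=10,
            usable=np.ones(n, dtype=bool),
            degenerate=np.zeros(n, dtype=bool),
        )

    @pytest.mark.parametrize(
        "h, expected",
        [([0, 0, 0, 0], 1.0), ([1, 1, 1, 1], 0.0), ([0, 1, 0, 1], 0.5)],
    )
    def test_fraction_of_similar_features(self, h, expected):
        assert sim_idx(self._sig(h)) == expected

    def test_half_significant_of_824(self):
        h = np.zeros(824, dtype=int)
        h[:412] = 1
        assert sim_idx(self._sig(h)) == 0.5

    def test_subset_restriction(self):
        sig = self._sig([0, 1, 0, 1])
        assert sim_idx(sig, [0, 2]) == 1.0
        assert sim_idx(sig, [1, 3]) == 0.0

    def test_empty_subset_is_an_error(self):
        with pytest.raises(AnalysisError):
            sim_idx(self._sig([0, 1]), [])

    def test_organelle_sim_idx_uses_channel_features(self, make_table):
        a = make_table("a", n_cells=50, seed=1)
        # shift only the ER feature (index 0 of the fixture schema)
        shift = np.zeros(a.schema.n_features)
        shift[0] = 5.0
        b = make_table("b", n_cells=50, shift=shift, seed=2)
        sig = feature_significance(a, b)
        per_channel = organelle_sim_idx(sig)
        assert per_channel["ER"] == 0.0
        assert per_channel["Golgi"] == 1.0


class TestPairwiseSimIdx:
    def test_self_comparison_is_one(self, make_table):
        a = make_table("a", seed=5)
        b = ProfileTable("b", a.schema, a.values.copy())
        assert pairwise_sim_idx(a, b) == 1.0

    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        schema = _schema(8)
        a = ProfileTable("a", schema, rng.normal(size=(9, 8)))
        b = ProfileTable("b", schema, rng.normal(0.5, 2.0, size=(7, 8)))
        assert pairwise_sim_idx(a, b) == pairwise_sim_idx(b, a)

    def test_disjoint_affected_sets_match_per_feature_oracle(self):
        """PSI of two compounds with disjoint strong effects equals the
        fraction computed by brute-force per-feature t-tests."""
        rng = np.random.default_rng(11)
        F, k, n = 60, 10, 120
        schema = _schema(F)
        shift_a = np.zeros(F)
        shift_a[:k] = 4.0
        shift_b = np.zeros(F)
        shift_b[k : 2 * k] = 4.0
        a = ProfileTable("a", schema, rng.normal(size=(n, F)) + shift_a)
        b = ProfileTable("b", schema, rng.normal(size=(n, F)) + shift_b)
        psi = pairwise_sim_idx(a, b)
        oracle_similar = sum(
            oracle_ttest_p(a.values[:, f], b.values[:, f]) >= 0.05 for f in range(F)
        )
        assert psi == pytest.approx(oracle_similar / F)
        # all 2k disjointly-affected features must differ
        assert psi <= (F - 2 * k) / F


class TestMahalanobis:
    def test_query_at_reference_mean_has_zero_distance(self, make_table):
        ref = make_table("ref", n_cells=50, seed=1)
        schema = ref.schema
        query = ProfileTable(
            "q", schema, np.vstack([ref.values.mean(axis=0), ref.values[0]])
        )
        _, per_cell, _ = mahalanobis_profile(ref, query, regularization=0.0,
                                             outlier_quantile=1.0)
        assert per_cell[0] == pytest.approx(0.0, abs=1e-10)

    def test_printed_covariance_oracle(self):
        """Reference with sample covariance [[2,0],[0,0.5]] and zero mean:
        the distance of (2,1) is sqrt(2^2/2 + 1^2/0.5) = 2."""
        schema = _schema(2)
        x = np.sqrt(3.0)
        y = np.sqrt(0.75)
        ref = ProfileTable(
            "ref", schema, np.array([[x, 0.0], [-x, 0.0], [0.0, y], [0.0, -y]])
        )
        np.testing.assert_allclose(
            np.cov(ref.values, rowvar=False), [[2.0, 0.0], [0.0, 0.5]], atol=1e-12
        )
        query = ProfileTable("q", schema, np.array([[2.0, 1.0]]))
        summary, per_cell, n_out = mahalanobis_profile(
            ref, query, regularization=0.0, outlier_quantile=1.0
        )
        assert per_cell[0] == pytest.approx(2.0, abs=1e-12)
        assert summary == pytest.approx(2.0, abs=1e-12)
        assert n_out == 0

    def test_euclidean_limit_for_identity_covariance(self):
        rng = np.random.default_rng(0)
        schema = _schema(3)
        ref = ProfileTable("ref", schema, rng.normal(size=(20000, 3)))
        query = ProfileTable("q", schema, np.array([[1.0, 0.0, 0.0]]))
        _, per_cell, _ = mahalanobis_profile(ref, query, regularization=0.0,
                                             outlier_quantile=1.0)
        assert per_cell[0] == pytest.approx(1.0, abs=0.05)

    @given(st.integers(0, 2**31 - 1))
    def test_invariant_under_per_feature_rescaling(self, seed):
        rng = np.random.default_rng(seed)
        schema = _schema(4)
        ref_vals = rng.normal(size=(40, 4))
        qry_vals = rng.normal(size=(10, 4))
        scale = rng.uniform(0.1, 10.0, size=4)
        offset = rng.normal(size=4)
        ref = ProfileTable("ref", schema, ref_vals)
        qry = ProfileTable("q", schema, qry_vals)
        ref_s = ProfileTable("ref", schema, ref_vals * scale + offset)
        qry_s = ProfileTable("q", schema, qry_vals * scale + offset)
        _, d1, _ = mahalanobis_profile(ref, qry, regularization=0.2)
        _, d2, _ = mahalanobis_profile(ref_s, qry_s, regularization=0.2)
        np.testing.assert_allclose(d1, d2, rtol=1e-8)

    def test_outlier_filtering_reduces_summary(self):
        rng = np.random.default_rng(2)
        schema = _schema(2)
        ref = ProfileTable("ref", schema, rng.normal(size=(200, 2)))
        qry_vals = rng.normal(size=(100, 2))
        qry_vals[0] = [50.0, 50.0]  # gross outlier
        qry = ProfileTable("q", schema, qry_vals)
        _, per_cell, n_out = mahalanobis_profile(
            ref, qry, regularization=0.0, outlier_quantile=0.95, aggregate="mean"
        )
        assert n_out >= 1
        assert per_cell[0] > 10


class TestDynamicRange:
    @pytest.mark.parametrize(
        "values, expected", [([0.2, 0.4, 0.8], 4.0), ([5, 5, 5], 1.0)]
    )
    def test_max_over_min(self, values, expected):
        assert dynamic_range(values) == pytest.approx(expected)

    def test_non_finite_values_are_excluded(self):
        assert dynamic_range([0.5, np.nan, 1.0, np.inf]) == 2.0

    def test_zero_value_rejected(self):
        with pytest.raises(AnalysisError):
            dynamic_range([0.0, 1.0])


class TestScreenSimilarity:
    def test_null_screen_calibrates_to_one_minus_alpha(self):
        """E[SimIdx] = 1 - alpha when treatment and DMSO share a law."""
        cfg = null_screen(3, n_moas=10, n_features=200, n_cells=40)
        profiles, ann, _ = simulate_screen(cfg)
        screen = screen_similarity(
            profiles, ann, compute_mahalanobis=False, per_compound=False
        )
        mean = screen.table["sim_idx"].mean()
        se = np.sqrt(0.95 * 0.05 / (10 * 200))
        assert mean == pytest.approx(0.95, abs=4 * se)

    def test_saturating_effect_drives_sim_idx_to_zero(self):
        from hcascreen import EffectSpec, SimulationConfig

        cfg = SimulationConfig(
            n_features=100,
            n_dmso_cells=500,
            n_cells_per_compound=500,
            effects=(EffectSpec("hit-all", frozenset(range(100)), 5.0),),
            seed=5,
        )
        profiles, ann, _ = simulate_screen(cfg)
        screen = screen_similarity(profiles, ann, compute_mahalanobis=False,
                                   per_compound=False)
        assert screen.table["sim_idx"].iloc[0] <= 0.05

    def test_single_moa_screen_has_one_row(self, make_table):
        from hcascreen import ScreenAnnotation

        profiles = {
            "DMSO": make_table("DMSO", seed=1),
            "c1": make_table("c1", seed=2),
        }
        ann = ScreenAnnotation({"DMSO": None, "c1": "moa A"})
        screen = screen_similarity(profiles, ann, compute_mahalanobis=False)
        assert len(screen.table) == 1
        assert screen.table["treatment_id"].iloc[0] == "moa A"
        assert set(screen.sig_vectors) == {"moa A"}

    def test_moa_pools_cells_across_compounds(self, make_table):
        from hcascreen import ScreenAnnotation

        profiles = {
            "DMSO": make_table("DMSO", n_cells=30, seed=1),
            "c1": make_table("c1", n_cells=10, seed=2),
            "c2": make_table("c2", n_cells=15, seed=3),
        }
        ann = ScreenAnnotation({"DMSO": None, "c1": "moa A", "c2": "moa A"})
        screen = screen_similarity(profiles, ann, compute_mahalanobis=False)
        assert screen.table["n_cells"].iloc[0] == 25

    def test_missing_control_is_an_error(self, make_table):
        from hcascreen import ScreenAnnotation

        profiles = {"c1": make_table("c1")}
        ann = ScreenAnnotation({"DMSO": None, "c1": "moa A"})
        with pytest.raises(AnalysisError, match="control"):
            screen_similarity(profiles, ann)
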