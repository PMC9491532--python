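import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from acoscale.simulate import ItemResponseTable
from acoscale.validity import (
    adjusted_r2,
    cohens_d,
    evaluate_validity,
    roc_auc,
    roc_curve_points,
    t_score,
    total_score,
    youden_cutoff,
)


def _table(responses, groups):
    return ItemResponseTable(np.asarray(responses, float), np.asarray(groups, dtype=object))


class TestTotalScore:
    def test_extremes(self):
        t = _table(np.zeros((3, 20)), ["control"] * 3)
        np.testing.assert_array_equal(total_score(t), 0)
        t = _table(np.full((2, 20), 4.0), ["control"] * 2)
        np.testing.assert_array_equal(total_score(t), 80)

    def test_prorating_scales_observed_mean(self):
        row = np.full(20, 2.0)
        row[3] = np.nan
        t = _table([row], ["control"])
        assert total_score(t, prorate=True)[0] == pytest.approx(40.0)

    def test_missing_without_prorate_raises(self):
        row = np.full(20, 2.0)
        row[0] = np.nan
        t = _table([row], ["control"])
        with pytest.raises(ValueError, match="prorate"):
            total_score(t)

    def test_excess_missingness_gives_nan(self):
        row = np.full(10, 2.0)
        row[:4] = np.nan
        t = _table([row], ["control"])
        assert np.isnan(total_score(t, prorate=True, max_missing_fraction=0.2)[0])


class TestCohensD:
    def test_printed_toy_example(self):
        scores = [10, 12, 14, 20, 22, 24]
        groups = ["control"] * 3 + ["patient"] * 3
        # pooled SD 2, mean difference 10 -> d = 5
        assert cohens_d(scores, groups) == pytest.approx(5.0, abs=1e-12)

    def test_unit_difference(self):
        rng = np.random.default_rng(0)
        con = rng.normal(0, 1, 20000)
        pat = rng.normal(1, 1, 20000)
        d = cohens_d(np.concatenate([con, pat]), ["control"] * 20000 + ["patient"] * 20000)
        assert d == pytest.approx(1.0, abs=0.05)

    def test_identical_groups_zero(self):
        scores = [1, 2, 3, 1, 2, 3]
        assert cohens_d(scores, ["control"] * 3 + ["patient"] * 3) == pytest.approx(0.0)

    def test_translation_and_scale_invariance(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(5, 2, 100)
        groups = np.where(rng.random(100) < 0.4, "patient", "control")
        d0 = cohens_d(scores, groups)
        assert cohens_d(scores + 7.3, groups) == pytest.approx(d0, abs=1e-10)
        assert cohens_d(scores * 2.5, groups) == pytest.approx(d0, abs=1e-10)


class TestAdjustedR2:
    def test_formula_arithmetic(self):
        # any data with R^2 = 0.5 at n = 101 must give 1 - 0.5*100/99
        # verified through the formula on a constructed two-point score
        rng = np.random.default_rng(2)
        scores = rng.normal(size=101)
        y = np.where(rng.random(101) < 0.5, "patient", "control")
        r = np.corrcoef(scores, (np.asarray(y) == "patient").astype(float))[0, 1]
        expected = 1 - (1 - r * r) * 100 / 99
        assert adjusted_r2(scores, y) == pytest.approx(expected, abs=1e-12)

    def test_matches_ols_oracle(self):
        import statsmodels.api as sm_api

        rng = np.random.default_rng(3)
        scores = rng.normal(size=200)
        y = (rng.random(200) < 0.3 + 0.1 * (scores > 0)).astype(float)
        groups = np.where(y == 1, "patient", "control")
        model = sm_api.OLS(y, sm_api.add_constant(scores)).fit()
        assert adjusted_r2(scores, groups) == pytest.approx(model.rsquared_adj, abs=1e-10)

    def test_independence_near_zero(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=5000)
        groups = np.where(rng.random(5000) < 0.5, "patient", "control")
        assert abs(adjusted_r2(scores, groups)) < 0.01

    def test_constant_scores_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            adjusted_r2([1, 1, 1, 1], ["control", "control", "patient", "patient"])


def _brute_force_auc(con, pat):
    wins = sum((p > c) + 0.5 * (p == c) for p in pat for c in con)
    return wins / (len(con) * len(pat))


class TestRocAuc:
    def test_disjoint_ranges_give_one(self):
        scores = [1, 2, 3, 10, 11, 12]
        groups = ["control"] * 3 + ["patient"] * 3
        auc, lo, hi = roc_auc(scores, groups)
        assert auc == 1.0
        assert lo <= 1.0 <= hi

    def test_identical_distributions_near_half(self):
        rng = np.random.default_rng(5)
        scores = rng.integers(0, 40, 4000)
        groups = np.where(rng.random(4000) < 0.5, "patient", "control")
        auc, _, _ = roc_auc(scores, groups)
        assert abs(auc - 0.5) < 0.03

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 100), st.integers(2, 100))
    def test_rank_formula_equals_pair_counting(self, seed, n_c, n_p):
        rng = np.random.default_rng(seed)
        con = rng.integers(0, 30, n_c)
        pat = rng.integers(5, 40, n_p)
        scores = np.concatenate([con, pat])
        groups = ["control"] * n_c + ["patient"] * n_p
        auc, _, _ = roc_auc(scores, groups)
        assert auc == pytest.approx(_brute_force_auc(con, pat), abs=1e-12)

    def test_ci_bounds_ordered_and_clipped(self):
        scores = [1, 2, 3, 3, 4, 5]
        groups = ["control"] * 3 + ["patient"] * 3
        auc, lo, hi = roc_auc(scores, groups)
        assert 0.0 <= lo <= auc <= hi <= 1.0


def _brute_force_youden(con, pat):
    # exhaustive scan in exact rational arithmetic (fractions)
    from fractions import Fraction

    candidates = np.unique(np.concatenate([con, pat]))
    candidates = np.concatenate([candidates, [candidates.max() + 1]])
    best = None
    for c in candidates:
        j = Fraction(int((pat >= c).sum()), len(pat)) + Fraction(
            int((con < c).sum()), len(con)
        )
        if best is None or j > best[1]:
            best = (c, j)
    return best[0]


class TestYouden:
    def test_printed_toy_example(self):
        # controls {1,2,3}, patients {3,4,5}: c=3 and c=4 tie at J=2/3,
        # the smaller cutoff wins (favoring sensitivity)
        scores = [1, 2, 3, 3, 4, 5]
        groups = ["control"] * 3 + ["patient"] * 3
        c, sens, spec = youden_cutoff(scores, groups)
        assert c == 3
        assert sens == pytest.approx(1.0)
        assert spec == pytest.approx(2 / 3)

    def test_disjoint_ranges_perfect_separation(self):
        scores = [1, 2, 3, 10, 11, 12]
        groups = ["control"] * 3 + ["patient"] * 3
        c, sens, spec = youden_cutoff(scores, groups)
        assert 3 < c <= 10
        assert sens == 1.0 and spec == 1.0

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(2, 80), st.integers(2, 80))
    def test_scan_equals_exhaustive_enumeration(self, seed, n_c, n_p):
        rng = np.random.default_rng(seed)
        con = rng.integers(0, 25, n_c)
        pat = rng.integers(5, 35, n_p)
        scores = np.concatenate([con, pat])
        groups = ["control"] * n_c + ["patient"] * n_p
        c, _, _ = youden_cutoff(scores, groups)
        assert c == _brute_force_youden(con, pat)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            youden_cutoff([1, 2, 3], ["control"] * 3)


class TestTScore:
    def test_reference_mean_maps_to_50(self):
        assert t_score(12.0, 12.0, 10.0) == 50.0

    def test_one_sd_above_maps_to_60(self):
        assert t_score(22.0, 12.0, 10.0) == 60.0

    def test_printed_cutoff_pairing(self):
        # a raw cutoff of 36 against reference mean 12, SD 10 is T = 74
        assert t_score(36.0, 12.0, 10.0) == 74.0

    def test_zero_sd_rejected(self):
        with pytest.raises(ValueError):
            t_score(10.0, 10.0, 0.0)


class TestEvaluateValidity:
    def test_full_panel_on_separated_synthetic_data(self, tiny_table):
        rep = evaluate_validity(tiny_table)
        assert rep.auc_ci_low <= rep.auc <= rep.auc_ci_high
        assert 0 <= rep.sensitivity <= 1 and 0 <= rep.specificity <= 1
        assert rep.cohens_d > 0.5  # shifted patient group must separate
        # cutoff T-score consistent with its raw value
        assert rep.cutoff_t == pytest.approx(
            t_score(rep.cutoff_raw, rep.reference_mean, rep.reference_sd)
        )

    def test_strong_general_factor_yields_clinical_utility(self):
        # a 20-item form with strong loadings and the 2.1-SD latent group
        # shift must separate groups clinically: AUC > 0.9 and d > 2
        from acoscale.simulate import DOMAINS, ScaleMap, TrueModel, simulate_responses
        from acoscale.validity import cohens_d

        sm = ScaleMap({f"i{k}": (DOMAINS[k // 5], 1) for k in range(20)})
        thr = np.tile([-0.2, 0.6, 1.3, 2.0], (20, 1))
        truth = TrueModel(
            sm, "hierarchical", np.full(20, 0.85), np.zeros(20), thr,
            group_shift=2.1, higher_order_loadings=np.full(4, 0.95),
        )
        t = simulate_responses(truth, 640, 160, seed=0)
        scores = t.responses.sum(axis=1)
        assert cohens_d(scores, t.group) > 2.0
        assert roc_auc(scores, t.group)[0] > 0.9

    def test_auc_shift_invariance(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=300)
        groups = np.where(rng.random(300) < 0.3, "patient", "control")
        a0 = roc_auc(scores, groups)[0]
        assert roc_auc(scores + 11.0, groups)[0] == pytest.approx(a0, abs=1e-12)
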