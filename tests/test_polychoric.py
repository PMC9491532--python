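import numpy as np
import pytest
from scipy.stats import multivariate_normal, norm

from acoscale.polychoric import (
    DegenerateItemError,
    PolychoricMatrix,
    bvn_cdf,
    estimate_thresholds,
    polychoric_matrix,
    polychoric_pair,
    smooth_to_psd,
)
from acoscale.simulate import make_default_true_model, simulate_responses


class TestBvnCdf:
    @pytest.mark.parametrize("rho", [-0.99, -0.95, -0.6, 0.0, 0.3, 0.6, 0.9, 0.925, 0.95, 0.99])
    def test_matches_scipy(self, rho):
        rng = np.random.default_rng(0)
        h = rng.uniform(-3.5, 3.5, 25)
        k = rng.uniform(-3.5, 3.5, 25)
        ref = np.array(
            [
                multivariate_normal.cdf([a, b], mean=[0, 0], cov=[[1, rho], [rho, 1]])
                for a, b in zip(h, k)
            ]
        )
        np.testing.assert_allclose(bvn_cdf(h, k, rho), ref, atol=1e-10)

    def test_infinite_arguments_reduce_to_marginals(self):
        assert bvn_cdf(np.inf, 0.5, 0.6) == pytest.approx(norm.cdf(0.5), abs=1e-12)
        assert bvn_cdf(-np.inf, 0.5, 0.6) == 0.0
        assert bvn_cdf(np.inf, np.inf, -0.4) == pytest.approx(1.0)


class TestThresholds:
    def test_uniform_counts_give_quantiles(self):
        thr = estimate_thresholds([20, 20, 20, 20, 20])
        np.testing.assert_allclose(
            thr, norm.ppf([0.2, 0.4, 0.6, 0.8]), atol=1e-12
        )
        np.testing.assert_allclose(thr, [-0.8416, -0.2533, 0.2533, 0.8416], atol=1e-4)

    def test_degenerate_item(self):
        with pytest.raises(DegenerateItemError):
            estimate_thresholds([100, 0, 0, 0, 0])

    def test_symmetric_counts_symmetric_thresholds(self):
        thr = estimate_thresholds([10, 20, 40, 20, 10])
        np.testing.assert_allclose(thr, -thr[::-1], atol=1e-12)

    def test_empty_trailing_category_gives_inf_sentinel(self):
        thr = estimate_thresholds([50, 50, 0, 0, 0])
        assert np.isfinite(thr[0])
        assert np.all(np.isposinf(thr[1:]))


def _ordinal_pair(rho, n, seed, cuts=(0.5, 0.75, 0.9, 0.97)):
    rng = np.random.default_rng(seed)
    z = rng.multivariate_normal([0, 0], [[1, rho], [rho, 1]], size=n)
    thr = norm.ppf(cuts)
    x = (z[:, 0, None] > thr).sum(1)
    y = (z[:, 1, None] > thr).sum(1)
    tab = np.zeros((5, 5))
    np.add.at(tab, (x, y), 1.0)
    ti = estimate_thresholds(np.bincount(x, minlength=5))
    tj = estimate_thresholds(np.bincount(y, minlength=5))
    return tab, ti, tj


class TestPolychoricPair:
    def test_consistency_at_null(self):
        tab, ti, tj = _ordinal_pair(0.0, 5000, seed=1)
        assert abs(polychoric_pair(tab, ti, tj)) < 0.05

    def test_recovers_moderate_correlation(self):
        tab, ti, tj = _ordinal_pair(0.6, 5000, seed=2)
        assert 0.55 <= polychoric_pair(tab, ti, tj) <= 0.65

    def test_diagonal_table_implies_high_rho(self):
        # all mass on the diagonal with uniform margins: the grid-search
        # oracle over coarse rho confirms the likelihood peaks near 1
        tab = np.diag([20.0, 20.0, 20.0, 20.0, 20.0])
        thr = norm.ppf([0.2, 0.4, 0.6, 0.8])
        rho_hat = polychoric_pair(tab, thr, thr)
        grid = np.arange(-0.95, 0.96, 0.05)

        def ll(r):
            from acoscale.polychoric import _cell_probabilities

            P = _cell_probabilities(thr, thr, r)
            return np.sum(tab * np.log(np.maximum(P, 1e-300)))

        best_grid = grid[np.argmax([ll(r) for r in grid])]
        assert rho_hat > 0.9
        assert rho_hat >= best_grid - 0.05

    def test_tetrachoric_reduction_matches_grid_oracle(self):
        # dichotomized bivariate normal: the 2x2-collapsed table must give
        # the tetrachoric value found by brute-force likelihood grid search
        rng = np.random.default_rng(5)
        z = rng.multivariate_normal([0, 0], [[1, 0.45], [0.45, 1]], size=4000)
        x = (z[:, 0] > 0.3).astype(int)
        y = (z[:, 1] > -0.2).astype(int)
        tab = np.zeros((5, 5))
        np.add.at(tab, (x, y), 1.0)
        ti = estimate_thresholds(np.bincount(x, minlength=5).astype(float))
        tj = estimate_thresholds(np.bincount(y, minlength=5).astype(float))
        rho_hat = polychoric_pair(tab, ti, tj)

        n11 = tab[1, 1]; n10 = tab[1, 0]; n01 = tab[0, 1]; n00 = tab[0, 0]
        a, b = ti[0], tj[0]
        grid = np.arange(-0.99, 0.995, 0.005)
        lls = []
        for r in grid:
            cov = [[1, r], [r, 1]]
            p00 = multivariate_normal.cdf([a, b], mean=[0, 0], cov=cov)
            p01 = norm.cdf(a) - p00
            p10 = norm.cdf(b) - p00
            p11 = 1 - p00 - p01 - p10
            probs = np.maximum([p00, p01, p10, p11], 1e-12)
            lls.append(
                n00 * np.log(probs[0]) + n01 * np.log(probs[1])
                + n10 * np.log(probs[2]) + n11 * np.log(probs[3])
            )
        oracle = grid[int(np.argmax(lls))]
        assert rho_hat == pytest.approx(oracle, abs=0.01)


@pytest.fixture(scope="module")
def independent_table():
    from acoscale.simulate import ScaleMap, TrueModel

    sm = ScaleMap(
        {
            f"i{k}": (d, 1)
            for k, d in enumerate(
                ["Identity"] * 2 + ["Self-direction"] * 2 + ["Empathy"] * 2 + ["Intimacy"] * 2
            )
        }
    )
    thr = np.tile([-1.0, -0.3, 0.3, 1.0], (8, 1))
    m = TrueModel(sm, "bifactor", np.zeros(8), np.zeros(8), thr, group_shift=0.0)
    return simulate_responses(m, 5000, 0, seed=21)


class TestPolychoricMatrix:
    def test_identity_structure_recovered(self, independent_table):
        pm = polychoric_matrix(independent_table)
        off = pm.rho[np.triu_indices(8, 1)]
        assert np.abs(off).max() < 0.05
        np.testing.assert_allclose(pm.rho, pm.rho.T)
        np.testing.assert_allclose(np.diag(pm.rho), 1.0)

    def test_subset_stability(self, independent_table):
        pm = polychoric_matrix(independent_table)
        sub_ids = pm.item_ids[2:6]
        direct = polychoric_matrix(independent_table, subset=sub_ids)
        np.testing.assert_allclose(
            pm.submatrix(sub_ids).rho, direct.rho, atol=1e-10
        )

    def test_respondent_order_invariance(self, independent_table):
        t = independent_table
        rng = np.random.default_rng(0)
        perm = rng.permutation(t.n_respondents)
        from acoscale.simulate import ItemResponseTable

        shuffled = ItemResponseTable(
            t.responses[perm], t.group[perm], item_ids=t.item_ids
        )
        a = polychoric_matrix(t, subset=t.item_ids[:4])
        b = polychoric_matrix(shuffled, subset=t.item_ids[:4])
        np.testing.assert_allclose(a.rho, b.rho, atol=1e-12)

    def test_estimates_track_population_matrix(self, tiny_model):
        from acoscale.simulate import implied_latent_correlation

        table = simulate_responses(tiny_model, 5000, 0, seed=31)
        pm = polychoric_matrix(table)
        pop = implied_latent_correlation(tiny_model)
        assert np.abs(pm.rho - pop).max() < 0.05

    def test_cross_domain_correlation_at_known_loading(self):
        # bifactor with g=0.7 everywhere: cross-domain latent correlation is
        # 0.7 * 0.7 = 0.49; the estimates should sit within +/-0.04 of it
        from acoscale.simulate import ScaleMap, TrueModel

        sm = ScaleMap(
            {
                f"i{k}": (d, 1)
                for k, d in enumerate(
                    ["Identity"] * 2 + ["Self-direction"] * 2 + ["Empathy"] * 2 + ["Intimacy"] * 2
                )
            }
        )
        thr = np.tile([-0.8, 0.0, 0.8, 1.6], (8, 1))
        m = TrueModel(sm, "bifactor", np.full(8, 0.7), np.zeros(8), thr, group_shift=0.0)
        table = simulate_responses(m, 5000, 0, seed=41)
        pm = polychoric_matrix(table)
        d = sm.domain_index()
        cross = d[:, None] != d[None, :]
        iu = np.triu_indices(8, 1)
        vals = pm.rho[iu][cross[iu]]
        assert np.all(np.abs(vals - 0.49) < 0.04)


class TestSmoothing:
    def test_indefinite_matrix_becomes_psd_with_unit_diagonal(self):
        bad = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(bad).min() < 0
        fixed, changed = smooth_to_psd(bad)
        assert changed
        assert np.linalg.eigvalsh(fixed).min() >= 0
        np.testing.assert_allclose(np.diag(fixed), 1.0)

    def test_psd_matrix_untouched(self):
        good = np.array([[1.0, 0.5], [0.5, 1.0]])
        fixed, changed = smooth_to_psd(good)
        assert not changed
        np.testing.assert_array_equal(fixed, good)
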