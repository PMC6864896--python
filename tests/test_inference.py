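"""Permutation test, streaming bootstrap ratios, score-age regressions."""

import numpy as np
import pytest
from scipy import stats

from structcov.inference import (
    WelfordAccumulator,
    _align_components,
    _renormalize,
    bootstrap_bsr,
    bsr_to_pvalue,
    permutation_test_components,
    regress_scores_on_age,
    threshold_bsr,
)
from structcov.plsc import cross_block_svd, plsc_fit
from tests.conftest import make_noise_blocks


class TestPermutationTest:
    def test_perfectly_coupled_attains_lower_bound(self, rng):
        from structcov.preprocess import PreprocessedBlock, center_normalize

        x = rng.standard_normal(50)
        pids = np.array([f"s{i}" for i in range(50)], dtype=object)
        xb = center_normalize(PreprocessedBlock(
            "X", x[:, None], np.array(["f"], object), pids))
        yb = center_normalize(PreprocessedBlock(
            "Y", x[:, None].copy(), np.array(["g"], object), pids))
        res = permutation_test_components(xb, yb, n_perm=200, seed=1)
        assert res.p_per_component[0] == pytest.approx(1 / 201)

    def test_monte_carlo_stability_when_doubling_n_perm(self, rng):
        xb, yb = make_noise_blocks(rng, n=30, p=5, q=4)
        p1 = permutation_test_components(xb, yb, n_perm=200, seed=5)
        p2 = permutation_test_components(xb, yb, n_perm=400, seed=5)
        a, b = p1.p_per_component[0], p2.p_per_component[0]
        assert abs(a - b) < 2 * np.sqrt(a * (1 - a) / 200) + 0.01

    def test_reproducible_under_seed(self, rng):
        xb, yb = make_noise_blocks(rng, n=25, p=4, q=3)
        r1 = permutation_test_components(xb, yb, n_perm=150, seed=9)
        r2 = permutation_test_components(xb, yb, n_perm=150, seed=9)
        assert np.array_equal(r1.p_per_component, r2.p_per_component)
        assert np.array_equal(r1.null_quantiles[0.95], r2.null_quantiles[0.95])


class TestWelford:
    def test_streaming_equals_two_pass(self, rng):
        xs = rng.standard_normal((50, 7, 3))
        acc = WelfordAccumulator((7, 3))
        for x in xs:
            acc.update(x)
        assert np.allclose(acc.mean, xs.mean(axis=0), rtol=1e-10)
        assert np.allclose(acc.variance, xs.var(axis=0, ddof=1), rtol=1e-8)

    def test_streaming_bootstrap_equals_stored_iterates(self, rng):
        # independent oracle: rerun the resampling loop, store every
        # aligned salience, and compare two-pass moments to the
        # streaming BSR ingredients
        xb, yb = make_noise_blocks(rng, n=30, p=6, q=4)
        model = plsc_fit(xb, yb)
        n_boot, seed = 120, 13
        res = bootstrap_bsr(xb, yb, model, n_boot=n_boot, seed=seed)
        K = model.n_components
        stored_U, stored_V = [], []
        for b in range(n_boot):
            rgen = np.random.default_rng([seed, 5, b, 0])
            idx = rgen.integers(0, 30, size=30)
            Xb = _renormalize(xb.values[idx])
            Yb = _renormalize(yb.values[idx])
            Ub, db, Vb = cross_block_svd(Xb, Yb, fix_signs=False)
            Ub, Vb = _align_components(Ub[:, :K], Vb[:, :K], model.U, model.V,
                                       "sign")
            stored_U.append(Ub)
            stored_V.append(Vb)
        stored_U = np.asarray(stored_U)
        stored_V = np.asarray(stored_V)
        assert res.n_redrawn == 0
        assert np.allclose(res.boot_mean_X, stored_U[:, :, 0].mean(0), rtol=1e-8)
        assert np.allclose(
            res.boot_se_X, stored_U[:, :, 0].std(0, ddof=1), rtol=1e-8
        )
        assert np.allclose(res.boot_mean_Y, stored_V[:, :, 0].mean(0), rtol=1e-8)
        assert np.allclose(
            res.boot_se_Y, stored_V[:, :, 0].std(0, ddof=1), rtol=1e-8
        )

    def test_bootstrap_reproducible_under_seed(self, rng):
        xb, yb = make_noise_blocks(rng, n=25, p=5, q=3)
        model = plsc_fit(xb, yb)
        r1 = bootstrap_bsr(xb, yb, model, n_boot=100, seed=4)
        r2 = bootstrap_bsr(xb, yb, model, n_boot=100, seed=4)
        assert np.array_equal(r1.bsr_X, r2.bsr_X)
        assert np.array_equal(r1.bsr_Y, r2.bsr_Y)


class TestBSRMapping:
    def test_z_score_style_thresholds(self):
        # the analytic BSR -> p mapping: 1.96 -> .05, 3 -> .0027
        assert bsr_to_pvalue(1.96) == pytest.approx(0.05, abs=1e-4)
        assert bsr_to_pvalue(3.0) == pytest.approx(0.0027, abs=1e-4)
        assert bsr_to_pvalue(0.0) == 1.0

    def test_decreasing_and_symmetric(self):
        grid = np.linspace(0.1, 5, 40)
        p = bsr_to_pvalue(grid)
        assert np.all(np.diff(p) < 0)
        assert np.allclose(bsr_to_pvalue(-grid), p)

    def test_threshold_boundary_inclusive(self):
        res = type("R", (), {})()
        res.bsr_X = np.array([-3.2, 2.9, 3.0])
        res.bsr_Y = np.array([1.96, -1.95])
        sx, sy = threshold_bsr(res, cutoff=3.0)
        assert list(sx) == [True, False, True]
        sx196, sy196 = threshold_bsr(res, cutoff=1.96)
        assert np.all(sx196[sx])  # cutoff-3 mask nested in cutoff-1.96 mask


class TestScoreAgeRegression:
    def test_noiseless_linear_prefers_linear(self, rng):
        age = rng.uniform(20, 90, 40)
        fit = regress_scores_on_age(2.0 - 0.03 * age, age)
        assert fit.preferred == "linear"
        assert fit.p_linear < 1e-10

    def test_pure_quadratic_prefers_quadratic(self, rng):
        age = rng.uniform(20, 90, 40)
        ac = age - age.mean()
        fit = regress_scores_on_age(ac**2, age)
        assert fit.preferred == "quadratic"

    def test_f_statistics_match_anova_oracle(self, rng):
        age = rng.uniform(20, 90, 60)
        score = 0.5 * age + 3 * rng.standard_normal(60)
        fit = regress_scores_on_age(score, age)
        # hand-computed sums-of-squares decomposition
        ac = age - age.mean()
        for D, f_obs, dfm in [
            (np.column_stack([np.ones(60), ac]), fit.f_linear, 1),
            (np.column_stack([np.ones(60), ac, ac**2]), fit.f_quadratic, 2),
        ]:
            beta = np.linalg.solve(D.T @ D, D.T @ score)
            yhat = D @ beta
            ss_model = np.sum((yhat - score.mean()) ** 2)
            ss_resid = np.sum((score - yhat) ** 2)
            f = (ss_model / dfm) / (ss_resid / (60 - dfm - 1))
            assert f_obs == pytest.approx(f, abs=1e-8)
        assert fit.df_linear == (1, 58)
        assert fit.df_quadratic == (2, 57)


class TestAlignment:
    def test_sign_alignment_restores_flipped_component(self, rng):
        xb, yb = make_noise_blocks(rng, n=20, p=5, q=4)
        model = plsc_fit(xb, yb)
        Ub, Vb = _align_components(
            -model.U, -model.V, model.U, model.V, "sign"
        )
        assert np.allclose(Ub, model.U)
        assert np.allclose(Vb, model.V)

    def test_procrustes_recovers_rotation(self, rng):
        xb, yb = make_noise_blocks(rng, n=20, p=5, q=4)
        model = plsc_fit(xb, yb)
        theta = 0.3
        K = model.n_components
        Q = np.eye(K)
        Q[:2, :2] = [[np.cos(theta), -np.sin(theta)],
                     [np.sin(theta), np.cos(theta)]]
        Ub, Vb = _align_components(
            model.U @ Q, model.V @ Q, model.U, model.V, "procrustes"
        )
        assert np.allclose(Ub, model.U, atol=1e-8)
        assert np.allclose(Vb, model.V, atol=1e-8)
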