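"""Per-feature age GLMs, permutation p-values, TFCE, FWE, gradients."""

import numpy as np
import pytest

from structcov.data_io import TemplateMask, VoxelMetricMatrix
from structcov.simulate import effect_field
from structcov.univariate import (
    ModelError,
    fit_age_model,
    fwe_maxstat_pvalues,
    gradient_profile,
    permutation_pvalue,
    tfce_enhance,
    voxelwise_age_glm,
)


def covariates(rng, n=60):
    age = rng.uniform(20, 90, n)
    sex = rng.integers(0, 2, n).astype(float)
    return age, sex


def planted_response(rng, age, sex, beta):
    """y with standardized age coefficient exactly beta.

    Noise is drawn, then orthogonalized against age and sex and scaled
    so that var(y) = 1; the multiple-regression coefficient of z(age)
    on z(y) is then exactly beta (closed-form construction).
    """
    n = len(age)
    z = (age - age.mean()) / age.std()
    zq = z**2 - np.mean(z**2)
    e = rng.standard_normal(n)
    Q, _ = np.linalg.qr(np.column_stack([np.ones(n), z, zq, sex]))
    e -= Q @ (Q.T @ e)
    e /= e.std()
    return beta * z + np.sqrt(1 - beta**2) * e


class TestFitAgeModel:
    def test_standardized_beta_recovered_exactly(self, rng):
        age, sex = covariates(rng)
        y = planted_response(rng, age, sex, -0.5)
        res = fit_age_model(y, age, sex, n_perm=200, seed=1)
        assert res.model_form == "linear"
        assert abs(res.std_beta_age - (-0.5)) < 1e-10

    def test_planted_quadratic_detected(self, rng):
        age, sex = covariates(rng, n=80)
        ac = age - age.mean()
        y = 0.8 * (ac**2 - np.mean(ac**2)) / np.std(ac**2) \
            + 0.3 * rng.standard_normal(80)
        res = fit_age_model(y, age, sex, n_perm=500, seed=2)
        assert res.model_form == "quadratic"
        assert res.p_perm_age2 < 0.05

    def test_noiseless_linear_never_keeps_quadratic(self, rng):
        age, sex = covariates(rng)
        y = -0.4 * (age - age.mean())
        res = fit_age_model(y, age, sex, alpha=0.5, n_perm=200, seed=3)
        assert res.model_form == "linear"

    def test_standardized_beta_affine_invariant(self, rng):
        age, sex = covariates(rng)
        y = planted_response(rng, age, sex, 0.3)
        r1 = fit_age_model(y, age, sex, n_perm=200, seed=4)
        r2 = fit_age_model(5.0 * y + 100.0, age, sex, n_perm=200, seed=4)
        assert abs(r1.std_beta_age - r2.std_beta_age) < 1e-10

    def test_zero_age_variance_rejected(self, rng):
        sex = rng.integers(0, 2, 20).astype(float)
        with pytest.raises(ModelError):
            fit_age_model(rng.standard_normal(20), np.full(20, 50.0), sex)


class TestPermutationPvalue:
    def test_paper_literal_counting(self):
        assert permutation_pvalue(2.5, [1, 2, 3, 4], "paper_literal") == 0.5

    def test_paper_literal_extreme_is_zero(self):
        assert permutation_pvalue(-9.0, [1, 2, 3, 4], "paper_literal") == 0.0

    def test_two_sided_at_null_center(self, rng):
        t_null = rng.standard_normal(999)
        assert permutation_pvalue(0.0, t_null, "two_sided") == 1.0

    def test_two_sided_add_one_bound(self, rng):
        t_null = rng.standard_normal(400)
        p = permutation_pvalue(99.0, t_null, "two_sided")
        assert p == pytest.approx(1 / 401)


class TestVoxelwiseGLM:
    def make_matrix(self, vals, dims):
        tpl = TemplateMask(dims, np.ones(dims, bool))
        pids = np.array([f"s{i}" for i in range(vals.shape[0])], dtype=object)
        return VoxelMetricMatrix("MD", pids, tpl, vals)

    def test_matches_single_feature_loop_oracle(self, rng):
        age, sex = covariates(rng, n=40)
        vals = 5 + rng.standard_normal((40, 12))
        m = self.make_matrix(vals, (3, 2, 2))
        batched = voxelwise_age_glm(m, age, sex).stat
        import statsmodels.api as sm

        ac = age - age.mean()
        for v in range(12):
            fit = sm.OLS(vals[:, v], sm.add_constant(
                np.column_stack([ac, sex]))).fit()
            assert abs(batched[v] - fit.tvalues[1]) < 1e-8

    def test_planted_voxel_has_max_t(self, rng):
        age, sex = covariates(rng, n=50)
        z = (age - age.mean()) / age.std()
        vals = 5 + 0.1 * rng.standard_normal((50, 8))
        vals[:, 5] += 0.8 * z
        m = self.make_matrix(vals, (2, 2, 2))
        stat = voxelwise_age_glm(m, age, sex).stat
        assert np.argmax(np.abs(stat)) == 5

    def test_effect_signs(self, rng):
        age, sex = covariates(rng, n=50)
        z = (age - age.mean()) / age.std()
        vals = 5 + 0.1 * rng.standard_normal((50, 2))
        vals[:, 0] -= 0.5 * z  # FA-like decline
        vals[:, 1] += 0.5 * z  # MD-like rise
        m = self.make_matrix(vals, (2, 1, 1))
        stat = voxelwise_age_glm(m, age, sex).stat
        assert stat[0] < 0 < stat[1]


class TestTFCE:
    def full_template(self, dims=(3, 3, 3)):
        return TemplateMask(dims, np.ones(dims, bool))

    def test_single_voxel_closed_sum(self):
        tpl = self.full_template()
        t = np.zeros(27)
        t[13] = 2.0
        enh = tfce_enhance(t, tpl, dh=0.1)
        oracle = sum((0.1 * i) ** 2 * 0.1 for i in range(1, 21))
        assert enh[13] == pytest.approx(oracle, rel=1e-9)
        assert np.all(enh[np.arange(27) != 13] == 0)

    def test_zero_map_zero_output(self):
        tpl = self.full_template()
        assert np.all(tfce_enhance(np.zeros(27), tpl) == 0)

    def test_extent_scaling_between_clusters(self):
        # height-2 clusters of sizes 1 and 8 on a 6x2x2 grid, disjoint:
        # the large cluster's enhancement is 8^E times the singleton's
        tpl = self.full_template((6, 2, 2))
        vol = np.zeros((6, 2, 2))
        vol[0, 0, 0] = 2.0
        vol[4:6, :, :] = 2.0
        t = vol.reshape(-1)[tpl.voxel_order]
        enh = tfce_enhance(t, tpl, E=0.5, H=2.0, dh=0.1)
        vol_e = np.zeros(24)
        vol_e[tpl.voxel_order] = enh
        vol_e = vol_e.reshape(6, 2, 2)
        assert vol_e[5, 0, 0] == pytest.approx(vol_e[0, 0, 0] * 8**0.5, rel=1e-9)

    def test_negative_tail_antisymmetric(self, rng):
        tpl = self.full_template()
        t = rng.standard_normal(27)
        assert np.allclose(tfce_enhance(-t, tpl), -tfce_enhance(t, tpl))

    def test_monotone_under_scaling(self, rng):
        tpl = self.full_template()
        t = np.abs(rng.standard_normal(27))
        e1 = tfce_enhance(t, tpl, dh=0.05)
        e2 = tfce_enhance(2.5 * t, tpl, dh=0.05)
        assert np.all(e2 >= e1 - 1e-12)


class TestFWE:
    def test_add_one_lower_bound(self, rng):
        # statistic above every permuted max -> p = 1/(B+1)
        age, sex = covariates(rng, n=60)
        z = (age - age.mean()) / age.std()
        vals = 5 + 0.2 * rng.standard_normal((60, 12))
        vals[:, 4] += 2.0 * z
        tpl = TemplateMask((3, 2, 2), np.ones((3, 2, 2), bool))
        pids = np.array([f"s{i}" for i in range(60)], dtype=object)
        m = VoxelMetricMatrix("MD", pids, tpl, vals)
        res = fwe_maxstat_pvalues(m, age, sex, B=100, seed=1, enhance=False)
        assert res.p_fwe[4] == pytest.approx(1 / 101)

    def test_planted_effect_survives_tfce_correction(self, rng):
        age, sex = covariates(rng, n=80)
        z = (age - age.mean()) / age.std()
        vals = 5 + 0.5 * rng.standard_normal((80, 27))
        vals[:, 13] += 1.0 * z
        tpl = TemplateMask((3, 3, 3), np.ones((3, 3, 3), bool))
        pids = np.array([f"s{i}" for i in range(80)], dtype=object)
        m = VoxelMetricMatrix("MD", pids, tpl, vals)
        res = fwe_maxstat_pvalues(m, age, sex, B=200, seed=2, enhance=True)
        assert res.p_fwe[13] < 0.05

    def test_pvalues_monotone_in_statistic(self, rng):
        age, sex = covariates(rng, n=40)
        vals = 5 + rng.standard_normal((40, 12))
        tpl = TemplateMask((3, 2, 2), np.ones((3, 2, 2), bool))
        pids = np.array([f"s{i}" for i in range(40)], dtype=object)
        m = VoxelMetricMatrix("MD", pids, tpl, vals)
        res = fwe_maxstat_pvalues(m, age, sex, B=100, seed=3, enhance=False)
        order = np.argsort(np.abs(res.stat))
        assert np.all(np.diff(res.p_fwe[order]) <= 1e-12)


class TestGradientProfile:
    def test_constant_field_flat(self):
        tpl = TemplateMask((4, 5, 3), np.ones((4, 5, 3), bool))
        prof = gradient_profile(np.full(60, 0.3), tpl, "posterior-anterior")
        assert np.allclose(prof.statistic, 0.3)

    def test_planted_axis_strictly_increasing(self):
        dims = (4, 6, 3)
        tpl = TemplateMask(dims, np.ones(dims, bool))
        field = effect_field(dims, "posterior-anterior", 0.8)
        r_map = field.reshape(-1)[tpl.voxel_order]
        prof = gradient_profile(r_map, tpl, "posterior-anterior")
        assert np.all(np.diff(prof.statistic) > 0)

    def test_medial_lateral_reported_outward(self):
        dims = (6, 3, 3)
        tpl = TemplateMask(dims, np.ones(dims, bool))
        field = effect_field(dims, "medial-lateral", 1.0)
        prof = gradient_profile(field.reshape(-1)[tpl.voxel_order], tpl,
                                "medial-lateral")
        assert np.all(np.diff(prof.slice_index) > 0)  # distances outward
        assert np.all(np.diff(prof.statistic) > 0)

    def test_empty_slice_is_missing_not_zero(self):
        mask = np.ones((3, 4, 2), bool)
        mask[:, 2, :] = False
        tpl = TemplateMask((3, 4, 2), mask)
        prof = gradient_profile(np.full(tpl.n_voxels, 0.5), tpl,
                                "posterior-anterior")
        assert np.isnan(prof.statistic[2])
        assert prof.n_voxels[2] == 0
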