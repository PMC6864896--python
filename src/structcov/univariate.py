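"""Per-feature age models and their permutation inference.

Regional (ROI) analysis fits ``y ~ intercept + age_c + age_c^2 + sex``
per feature, drops the quadratic term when its permutation p-value is
not significant, and reports standardized betas.  Voxelwise analysis
runs the same linear model batched over all voxels, with
threshold-free cluster enhancement (TFCE) and max-statistic
family-wise-error correction over row permutations of age
(Freedman-Lane residual scheme, so the sex covariate is respected
under permutation).  Slice-wise gradient profiles summarize the
spatial organization of age effects along the anatomical axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from structcov.data_io import TemplateMask, VoxelMetricMatrix, devectorize_map
from structcov.simulate import AXIS_DIRECTIONS, ConfigurationError


class ModelError(ValueError):
    pass


@dataclass
class GLMResult:
    """Selected age model for one feature.

    ``p_perm`` is the permutation p-value of the (linear) age term in
    the selected model; quadratic fields are ``None`` when the model
    form is linear.
    """

    feature_id: str
    model_form: str  # "linear" or "quadratic"
    std_beta_age: float
    t_age: float
    p_perm: float
    n_perm: int
    std_beta_age2: float | None = None
    t_age2: float | None = None
    p_perm_age2: float | None = None


@dataclass
class VoxelStatMap:
    template: TemplateMask
    stat: np.ndarray          # per-voxel t (or TFCE-enhanced) statistic
    kind: str = "t"
    p_fwe: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stat.shape != (self.template.n_voxels,):
            raise ModelError("stat length does not match template voxel count")
        if self.p_fwe is not None and self.p_fwe.shape != self.stat.shape:
            raise ModelError("p_fwe length does not match stat")


@dataclass
class GradientProfile:
    """Per-slice summary of an age-effect map along one anatomical axis.

    Slices containing no masked voxels carry NaN (a missing marker),
    never 0.  For the medial-lateral axis, ``slice_index`` holds the
    distance of each slice pair from the mid-sagittal plane, reported
    outward.
    """

    axis: str
    slice_index: np.ndarray
    statistic: np.ndarray
    n_voxels: np.ndarray


# ---------------------------------------------------------------------------
# linear-model machinery
# ---------------------------------------------------------------------------


def _design(age: np.ndarray, sex: np.ndarray, quadratic: bool) -> tuple:
    """Design matrix [1, age_c, (age_c^2 centered,) sex]; returns (D, age_col)."""
    age = np.asarray(age, dtype=float)
    sex = np.asarray(sex, dtype=float)
    ac = age - age.mean()
    cols = [np.ones_like(ac), ac]
    if quadratic:
        q = ac**2
        cols.append(q - q.mean())
    cols.append(sex)
    D = np.column_stack(cols)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        raise ModelError("rank-deficient design (constant age or sex collinear)")
    return D, 1


def _batched_t(D: np.ndarray, Y: np.ndarray, term: int) -> np.ndarray:
    """t-statistics of one design term for every column of Y at once."""
    n, k = D.shape
    DtD_inv = np.linalg.inv(D.T @ D)
    beta = DtD_inv @ (D.T @ Y)
    resid = Y - D @ beta
    dof = n - k
    sigma2 = np.sum(resid**2, axis=0) / dof
    se = np.sqrt(np.clip(sigma2 * DtD_inv[term, term], 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta[term] / se, 0.0)
    return t


def _standardized_betas(D: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Coefficients with response and non-intercept predictors z-scored."""
    Dz = D.copy()
    for j in range(1, D.shape[1]):
        sd = D[:, j].std()
        Dz[:, j] = (D[:, j] - D[:, j].mean()) / sd
    ysd = y.std()
    yz = (y - y.mean()) / ysd if ysd > 0 else y - y.mean()
    beta, *_ = np.linalg.lstsq(Dz, yz, rcond=None)
    return beta


def _freedman_lane_null(
    D: np.ndarray,
    Y: np.ndarray,
    term: int,
    n_perm: int,
    seed: int,
    reducer=None,
) -> np.ndarray:
    """Null t-values for one term by Freedman-Lane residual permutation.

    The reduced model (all terms but ``term``) is fitted once; each
    iteration permutes its residual rows, rebuilds a surrogate
    response, and recomputes the full-model t.  ``reducer`` optionally
    maps the per-column t-vector of each iteration to a scalar (e.g.
    the image-wide max statistic).
    """
    Dr = np.delete(D, term, axis=1)
    beta_r, *_ = np.linalg.lstsq(Dr, Y, rcond=None)
    fitted = Dr @ beta_r
    resid = Y - fitted
    n = Y.shape[0]
    out = []
    for b in range(n_perm):
        rng = np.random.default_rng([seed, 6, b])
        Ystar = fitted + resid[rng.permutation(n)]
        t = _batched_t(D, Ystar, term)
        out.append(reducer(t) if reducer is not None else t)
    return np.asarray(out)


def permutation_pvalue(
    t_obs: float, t_null: np.ndarray, mode: str = "two_sided"
) -> float:
    """Permutation p-value of an observed t against its null sample.

    ``two_sided`` (default): (#{|t_null| >= |t_obs|} + 1) / (B + 1).
    ``paper_literal``: #{t_null < t_obs} / B — the one-sided
    lower-tail proportion without the add-one correction, in which a
    small p flags a strongly *negative* effect.
    """
    t_null = np.asarray(t_null, dtype=float)
    if t_null.size == 0:
        raise ModelError("t_null must be non-empty")
    B = t_null.size
    if mode == "two_sided":
        return float((np.sum(np.abs(t_null) >= abs(t_obs)) + 1) / (B + 1))
    if mode == "paper_literal":
        return float(np.sum(t_null < t_obs) / B)
    raise ModelError(f"unknown mode {mode!r}")


def fit_age_model(
    feature: np.ndarray,
    age: np.ndarray,
    sex: np.ndarray,
    alpha: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    feature_id: str = "feature",
    mode: str = "two_sided",
) -> GLMResult:
    """Per-feature age model with permutation-based quadratic selection.

    The full model ``y ~ 1 + age_c + age_c^2 + sex`` is fitted first;
    if the quadratic term's permutation p-value is >= ``alpha`` the
    model is refitted without it.  Standardized betas are computed on
    the z-scored response and predictors of the selected model.
    """
    y = np.asarray(feature, dtype=float)
    n = len(y)
    if n < 10:
        raise ModelError("need at least 10 participants")
    if np.asarray(age, dtype=float).std() == 0:
        raise ModelError("age has zero variance")
    Dq, _ = _design(age, sex, quadratic=True)
    Y = y[:, None]
    # degenerate guard: if the linear model already fits to machine
    # precision, residual-based quadratic statistics are meaningless
    Dl = _design(age, sex, quadratic=False)[0]
    beta_l, *_ = np.linalg.lstsq(Dl, y, rcond=None)
    ss_res = float(np.sum((y - Dl @ beta_l) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_res <= 1e-12 * max(ss_tot, 1e-300):
        t_q, p_q = 0.0, 1.0
    else:
        t_q = float(_batched_t(Dq, Y, 2)[0])
        null_q = _freedman_lane_null(Dq, Y, 2, n_perm, seed)[:, 0]
        p_q = permutation_pvalue(t_q, null_q, mode=mode)
    quadratic = p_q < alpha
    D = Dq if quadratic else _design(age, sex, quadratic=False)[0]
    t_age = float(_batched_t(D, Y, 1)[0])
    null_a = _freedman_lane_null(D, Y, 1, n_perm, seed + 1)[:, 0]
    p_age = permutation_pvalue(t_age, null_a, mode=mode)
    betas = _standardized_betas(D, y)
    if quadratic:
        return GLMResult(
            feature_id=feature_id,
            model_form="quadratic",
            std_beta_age=float(betas[1]),
            t_age=t_age,
            p_perm=p_age,
            n_perm=n_perm,
            std_beta_age2=float(betas[2]),
            t_age2=t_q,
            p_perm_age2=p_q,
        )
    return GLMResult(
        feature_id=feature_id,
        model_form="linear",
        std_beta_age=float(betas[1]),
        t_age=t_age,
        p_perm=p_age,
        n_perm=n_perm,
    )


# ---------------------------------------------------------------------------
# voxelwise analysis
# ---------------------------------------------------------------------------


def voxelwise_age_glm(
    matrix: VoxelMetricMatrix,
    age: np.ndarray,
    sex: np.ndarray,
    quadratic: bool = False,
) -> VoxelStatMap:
    """Batched per-voxel t-map for the age (or age^2) contrast.

    Same linear model as :func:`fit_age_model` without model selection:
    ``quadratic=False`` tests the linear age term in the linear model,
    ``quadratic=True`` the age^2 term in the quadratic model.
    """
    if len(np.asarray(age)) != matrix.values.shape[0]:
        raise ModelError("matrix and covariates are not aligned")
    D, _ = _design(age, sex, quadratic=quadratic)
    term = 2 if quadratic else 1
    t = _batched_t(D, matrix.values, term)
    return VoxelStatMap(template=matrix.template, stat=t, kind="t")


_CONNECTIVITY = ndimage.generate_binary_structure(3, 1)  # 6-neighbour


def _tfce_one_sided(vol: np.ndarray, E: float, H: float, dh: float) -> np.ndarray:
    out = np.zeros_like(vol)
    top = vol.max()
    if top <= 0:
        return out
    n_steps = int(np.floor(top / dh + 1e-9))
    for i in range(1, n_steps + 1):
        h = i * dh
        supra = vol >= h - 1e-12 * top
        labels, n_lab = ndimage.label(supra, structure=_CONNECTIVITY)
        if n_lab:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            out += np.where(supra, (sizes[labels] ** E) * (h**H) * dh, 0.0)
    return out


def tfce_enhance(
    t_map: np.ndarray,
    template: TemplateMask,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a signed per-voxel map.

    enhanced(v) = sum over thresholds h (from dh up to the map maximum,
    step dh) of extent(v, h)^E * h^H * dh, where extent is the size of
    the 6-connected supra-threshold cluster containing v.  The negative
    tail is enhanced on the negated map and subtracted, so the output
    is signed.  ``dh`` defaults to max|t| / 100.
    """
    t_map = np.asarray(t_map, dtype=float)
    if t_map.shape != (template.n_voxels,):
        raise ModelError("t_map length does not match template")
    peak = np.max(np.abs(t_map)) if t_map.size else 0.0
    if peak == 0:
        return np.zeros_like(t_map)
    step = dh if dh is not None else peak / 100.0
    if step <= 0:
        raise ModelError("dh must be > 0")
    vol = devectorize_map(t_map, template, fill=0.0)
    pos = _tfce_one_sided(np.clip(vol, 0, None), E, H, step)
    neg = _tfce_one_sided(np.clip(-vol, 0, None), E, H, step)
    enhanced = pos - neg
    return enhanced.reshape(-1)[template.voxel_order]


def fwe_maxstat_pvalues(
    matrix: VoxelMetricMatrix,
    age: np.ndarray,
    sex: np.ndarray,
    B: int = 10_000,
    enhance: bool = True,
    seed: int = 0,
    quadratic: bool = False,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
) -> VoxelStatMap:
    """Family-wise-error corrected voxelwise p-values by the max statistic.

    Each of ``B`` Freedman-Lane permutations of the age term yields a
    permuted statistic map (TFCE-enhanced when ``enhance``); every
    voxel's corrected p is (#{permutation max-|statistic| >=
    |statistic(v)|} + 1) / (B + 1).
    """
    if B < 100:
        raise ModelError("B must be >= 100")
    obs = voxelwise_age_glm(matrix, age, sex, quadratic=quadratic)
    tpl = matrix.template
    if enhance:
        stat = tfce_enhance(obs.stat, tpl, E=E, H=H, dh=dh)
        # freeze the threshold step so permuted maps use the observed scale
        step = dh if dh is not None else (np.max(np.abs(obs.stat)) / 100.0 or 1.0)

        def stat_fn(t):
            return tfce_enhance(t, tpl, E=E, H=H, dh=step)
    else:
        stat = obs.stat

        def stat_fn(t):
            return t

    D, _ = _design(age, sex, quadratic=quadratic)
    term = 2 if quadratic else 1
    max_null = _freedman_lane_null(
        D,
        matrix.values,
        term,
        B,
        seed,
        reducer=lambda t: np.max(np.abs(stat_fn(t))),
    )
    p = (np.sum(max_null[:, None] >= np.abs(stat)[None, :], axis=0) + 1) / (B + 1)
    return VoxelStatMap(
        template=tpl,
        stat=stat,
        kind="tfce" if enhance else "t",
        p_fwe=p,
    )


# ---------------------------------------------------------------------------
# gradient profiles
# ---------------------------------------------------------------------------


def age_correlation_map(matrix: VoxelMetricMatrix, age: np.ndarray) -> np.ndarray:
    """Per-voxel Pearson correlation between the metric and age."""
    age = np.asarray(age, dtype=float)
    ac = age - age.mean()
    V = matrix.values - matrix.values.mean(axis=0, keepdims=True)
    denom = np.sqrt(np.sum(V**2, axis=0)) * np.sqrt(np.sum(ac**2))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(denom > 0, (V.T @ ac) / denom, 0.0)
    return r


def gradient_profile(
    r_map: np.ndarray,
    template: TemplateMask,
    axis: str,
    statistic: str = "mean_abs",
) -> GradientProfile:
    """Slice-wise strength of the age association along an anatomical axis.

    Default statistic is the mean |r| over masked voxels per slice
    (``statistic="mean_signed"`` averages signed r instead).  The
    medial-lateral axis is folded about the mid-sagittal plane and
    reported outward, pooling the paired left/right slices.
    """
    if axis not in AXIS_DIRECTIONS:
        raise ConfigurationError(f"unknown axis {axis!r}")
    if statistic not in ("mean_abs", "mean_signed"):
        raise ModelError(f"unknown statistic {statistic!r}")
    vals = np.abs(r_map) if statistic == "mean_abs" else np.asarray(r_map, float)
    vol = devectorize_map(vals, template, fill=np.nan)
    vol[~template.mask] = np.nan
    ax = AXIS_DIRECTIONS[axis]
    n = template.grid_dims[ax]
    if axis == "medial-lateral":
        mid = (n - 1) / 2.0
        dists = np.abs(np.arange(n) - mid)
        groups = {}
        for i, d in enumerate(dists):
            groups.setdefault(round(float(d), 6), []).append(i)
        keys = sorted(groups)
        stat, counts = [], []
        for d in keys:
            sl = np.concatenate(
                [np.take(vol, i, axis=ax).ravel() for i in groups[d]]
            )
            m = np.isfinite(sl)
            counts.append(int(m.sum()))
            stat.append(float(np.mean(sl[m])) if m.any() else np.nan)
        return GradientProfile(
            axis=axis,
            slice_index=np.asarray(keys, dtype=float),
            statistic=np.asarray(stat),
            n_voxels=np.asarray(counts),
        )
    stat, counts = [], []
    for i in range(n):
        sl = np.take(vol, i, axis=ax).ravel()
        m = np.isfinite(sl)
        counts.append(int(m.sum()))
        stat.append(float(np.mean(sl[m])) if m.any() else np.nan)
    return GradientProfile(
        axis=axis,
        slice_index=np.arange(n, dtype=float),
        statistic=np.asarray(stat),
        n_voxels=np.asarray(counts),
    )


__all__ = [
    "ModelError",
    "GLMResult",
    "VoxelStatMap",
    "GradientProfile",
    "fit_age_model",
    "permutation_pvalue",
    "voxelwise_age_glm",
    "tfce_enhance",
    "fwe_maxstat_pvalues",
    "age_correlation_map",
    "gradient_profile",
]
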