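"""Synthetic lifespan cohorts with planted gray/white-matter covariance.

The generator emulates the statistical structure of a cross-sectional
aging study: an age-stratified cohort (ages 20-94 by default, four
strata), regional cortical morphometry (thickness, surface area and
their product, volume), and a small 3D white-matter grid carrying FA
and MD fields.  A latent per-participant aging factor — standardized
age plus noise, scaled by ``coupling_strength`` — loads onto gray
matter through a planted salience vector and onto FA (negatively) and
MD (positively) through a planted voxel salience with anterior- and
superior-increasing spatial gradients.  Because the planted saliences,
effect maps, null features and the latent factor are all returned as
:class:`PlantedTruth`, every downstream stage (univariate GLMs,
template construction, PLSC, bootstrap) can be checked against ground
truth.

What this emulates and what it does not: the grid is an abstract voxel
lattice with no anatomy, tract geometry or partial-volume structure;
noise is i.i.d. Gaussian per feature with no spatial autocorrelation
beyond the planted gradients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from structcov.data_io import (
    DESIKAN_REGIONS,
    CohortTable,
    DataModelError,
    ROIMeasureTable,
    TemplateMask,
    VoxelMetricMatrix,
    WMHMask,
    build_template_mask,
    vectorize,
)

#: Age strata of the default study design: (n, mean age, SD age).
DEFAULT_STRATA = (
    (43, 27.58, 4.37),
    (46, 45.72, 5.36),
    (48, 61.23, 3.66),
    (49, 76.75, 5.87),
)

AXIS_DIRECTIONS = {
    "posterior-anterior": 1,
    "inferior-superior": 2,
    "medial-lateral": 0,
}

# Physical scale/location used to place standardized signals on realistic
# measurement scales (thickness mm, area mm^2, FA unitless, MD mm^2/s).
_SCALES = {
    "thickness": (2.5, 0.15),
    "area": (2000.0, 120.0),
    "fa": (None, 0.05),       # FA location is the spatial base field
    "md": (0.75e-3, 0.04e-3),
}

#: Loading amplitude of the latent factor (in residual-SD units per unit
#: salience norm); moderate coupling comparable to the planted age slopes.
_LATENT_AMPLITUDE = 3.0


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Study-design knobs for the synthetic cohort and datasets.

    Defaults reproduce the emulated study conditions: 186 participants
    in four age strata spanning 20-94 years, 34 hemisphere-averaged
    cortical regions, a 10 x 12 x 10 white-matter grid, and strong
    (0.9) cross-block coupling through the latent aging factor.
    """

    seed: int = 0
    n_participants: int = 186
    age_range: tuple[float, float] = (20.0, 94.0)
    group_strata: tuple | None = DEFAULT_STRATA
    n_rois: int = 34
    grid_dims: tuple[int, int, int] = (10, 12, 10)
    coupling_strength: float = 0.9
    gm_effect_map: np.ndarray | None = None
    wm_effect_field: np.ndarray | None = None
    quad_fraction: float = 0.25
    noise_sd: float = 1.0
    wmh_rate: float = 2.0  # ~0.4% of the default template, per participant
    sex_effect: float = 0.1
    null_roi_fraction: float = 0.1
    null_voxel_fraction: float = 0.1

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        lo, hi = self.age_range
        if not (0 < lo <= hi):
            raise ConfigurationError("age_range must satisfy 0 < min <= max")
        if any(d < 2 for d in self.grid_dims):
            raise ConfigurationError("grid_dims must all be >= 2")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ConfigurationError("coupling_strength must lie in [0, 1]")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")
        if not 0.0 <= self.quad_fraction <= 1.0:
            raise ConfigurationError("quad_fraction must lie in [0, 1]")
        if self.wmh_rate < 0:
            raise ConfigurationError("wmh_rate must be >= 0")
        if self.group_strata is not None:
            sizes = [s[0] for s in self.group_strata]
            if any(n <= 0 for n in sizes):
                raise ConfigurationError("stratum sizes must be positive")
            if any(s[2] <= 0 for s in self.group_strata):
                raise ConfigurationError("stratum age SDs must be > 0")
            if sum(sizes) != self.n_participants:
                raise ConfigurationError(
                    f"stratum sizes sum to {sum(sizes)}, "
                    f"expected n_participants={self.n_participants}"
                )
        if self.gm_effect_map is not None:
            self.gm_effect_map = np.asarray(self.gm_effect_map, dtype=float)
            if self.gm_effect_map.shape != (self.n_rois,):
                raise ConfigurationError("gm_effect_map must have length n_rois")
        if self.wm_effect_field is not None:
            self.wm_effect_field = np.asarray(self.wm_effect_field, dtype=float)
            if self.wm_effect_field.shape != tuple(self.grid_dims):
                raise ConfigurationError("wm_effect_field must match grid_dims")


def null_config(**overrides) -> SimulationConfig:
    """A configuration with no age effects and no cross-block coupling.

    Used for type-I-error and permutation-null calibration: every
    feature is pure noise.
    """
    cfg = SimulationConfig(
        coupling_strength=0.0,
        quad_fraction=0.0,
        sex_effect=0.0,
        **overrides,
    )
    cfg.gm_effect_map = np.zeros(cfg.n_rois)
    cfg.wm_effect_field = np.zeros(cfg.grid_dims)
    return cfg


@dataclass
class PlantedTruth:
    """Ground truth of a simulated dataset for parameter-recovery tests."""

    true_gm_salience: np.ndarray
    true_wm_salience: np.ndarray
    null_feature_ids: tuple
    latent_age_factor: np.ndarray

    def __post_init__(self) -> None:
        for v in (self.true_gm_salience, self.true_wm_salience):
            nrm = np.linalg.norm(v)
            if nrm > 0 and abs(nrm - 1.0) > 1e-8:
                raise DataModelError("planted saliences must have unit norm")


# ---------------------------------------------------------------------------
# cohort
# ---------------------------------------------------------------------------


def generate_cohort(config: SimulationConfig) -> CohortTable:
    """Draw a cohort: stratified truncated-normal ages, fair-coin sex.

    With ``group_strata`` given, each stratum contributes ``size`` ages
    from a normal with the stated mean/SD truncated to ``age_range``;
    without strata, ages are uniform over the range.  Deterministic
    under ``config.seed``.
    """
    rng = np.random.default_rng([config.seed, 0])
    lo, hi = config.age_range
    ages, labels = [], []
    if config.group_strata is None:
        if lo == hi:
            ages = np.full(config.n_participants, lo)
        else:
            ages = rng.uniform(lo, hi, size=config.n_participants)
        labels = None
    else:
        for i, (size, mu, sd) in enumerate(config.group_strata):
            a, b = (lo - mu) / sd, (hi - mu) / sd
            draw = stats.truncnorm.rvs(a, b, loc=mu, scale=sd, size=size,
                                       random_state=rng)
            ages.append(draw)
            labels.extend([f"stratum{i}"] * size)
        ages = np.concatenate(ages)
        labels = np.asarray(labels, dtype=object)
    sex = rng.integers(0, 2, size=config.n_participants)
    pid = np.asarray(
        [f"sub-{i + 1:04d}" for i in range(config.n_participants)], dtype=object
    )
    return CohortTable(participant_id=pid, age=ages, sex=sex, group_label=labels)


# ---------------------------------------------------------------------------
# spatial effect fields
# ---------------------------------------------------------------------------


def effect_field(
    grid_dims: tuple[int, int, int], direction: str, slope: float
) -> np.ndarray:
    """Per-voxel effect map varying linearly along a named anatomical axis.

    ``posterior-anterior`` ramps with the y coordinate, and
    ``inferior-superior`` with z, both normalized to [0, 1];
    ``medial-lateral`` ramps with absolute normalized distance from the
    mid-sagittal plane (so slope < 0 makes the effect maximal
    mid-sagittally).
    """
    if direction not in AXIS_DIRECTIONS:
        raise ConfigurationError(
            f"unknown direction {direction!r}; expected one of "
            f"{sorted(AXIS_DIRECTIONS)}"
        )
    if any(d < 2 for d in grid_dims):
        raise ConfigurationError("grid_dims must all be >= 2")
    axis = AXIS_DIRECTIONS[direction]
    n = grid_dims[axis]
    coord = np.arange(n, dtype=float)
    if direction == "medial-lateral":
        mid = (n - 1) / 2.0
        t = np.abs(coord - mid) / mid
    else:
        t = coord / (n - 1)
    shape = [1, 1, 1]
    shape[axis] = n
    return np.broadcast_to(
        (slope * t).reshape(shape), grid_dims
    ).copy()


def _edge_taper(n: int) -> np.ndarray:
    # Hann-like window in (0, 1]; low at the grid edges.
    return np.sin(np.pi * (np.arange(n) + 0.5) / n)


def _base_fa_field(grid_dims: tuple[int, int, int]) -> np.ndarray:
    """Deterministic spatial FA baseline: high centrally, ~0.18 at edges.

    Edge voxels sit near the 0.15 template threshold so that, with
    measurement noise, the all-participants FA > 0.15 rule excludes a
    realistic rim of voxels.
    """
    wx, wy, wz = (_edge_taper(n) for n in grid_dims)
    window = np.minimum(
        np.minimum(wx[:, None, None], wy[None, :, None]), wz[None, None, :]
    )
    return 0.16 + 0.34 * window


# ---------------------------------------------------------------------------
# coupled GM / WM dataset
# ---------------------------------------------------------------------------


def _roi_names(n_rois: int) -> np.ndarray:
    if n_rois == len(DESIKAN_REGIONS):
        return np.asarray(DESIKAN_REGIONS, dtype=object)
    return np.asarray([f"roi_{i:03d}" for i in range(n_rois)], dtype=object)


def generate_coupled_dataset(config: SimulationConfig, cohort: CohortTable):
    """Generate GM tables, WM metric matrices and the planted ground truth.

    Returns ``(thickness, area, volume, fa_matrix, md_matrix, template,
    truth)``.  Construction:

    * latent factor ``l = coupling_strength * std(z_age + 0.3 eps)`` —
      at coupling 0 the blocks share nothing;
    * thickness(i, j) = location + scale * (-A u*_j l_i + b_j z_i +
      q_j (z_i^2 - 1) + sex_effect * sex_i + noise_sd * eps), with
      ``u*`` the planted unit-norm GM salience and ``b`` the per-ROI
      standardized age slope (default -0.35 at the strongest ROI,
      proportional to ``u*``);
    * surface area generated independently with half the age slope;
      volume is the exact elementwise product thickness * area;
    * FA carries the same latent factor with negative sign through the
      planted voxel salience (anterior/superior gradient pattern), MD
      with positive sign; FA is clipped to [0, 1], MD kept positive;
    * features named in ``truth.null_feature_ids`` receive noise only.
    """
    if cohort.n != config.n_participants:
        raise ConfigurationError("cohort size does not match config")
    rng = np.random.default_rng([config.seed, 1])
    n = cohort.n
    z = (cohort.age - cohort.age.mean()) / cohort.age.std()
    zq = z**2 - np.mean(z**2)  # centered quadratic regressor
    sex = cohort.sex.astype(float)

    latent0 = z + 0.3 * rng.standard_normal(n)
    latent0 = (latent0 - latent0.mean()) / latent0.std()
    latent = config.coupling_strength * latent0

    # --- gray matter ------------------------------------------------------
    regions = _roi_names(config.n_rois)
    n_null_roi = int(round(config.null_roi_fraction * config.n_rois))
    null_roi_idx = rng.choice(config.n_rois, size=n_null_roi, replace=False)
    u = np.abs(rng.normal(1.0, 0.3, size=config.n_rois))
    u[null_roi_idx] = 0.0
    u /= np.linalg.norm(u)

    if config.gm_effect_map is None:
        b_gm = -0.35 * u / u.max() if u.max() > 0 else np.zeros(config.n_rois)
    else:
        b_gm = config.gm_effect_map.copy()
        b_gm[null_roi_idx] = 0.0

    quad_gm = np.zeros(config.n_rois)
    signal_rois = np.setdiff1d(np.arange(config.n_rois), null_roi_idx)
    n_quad = int(round(config.quad_fraction * signal_rois.size))
    if n_quad:
        qidx = rng.choice(signal_rois, size=n_quad, replace=False)
        quad_gm[qidx] = -0.2

    def gm_block(slope, quad, couple_amp):
        s = (
            couple_amp * np.outer(latent, u)
            + np.outer(z, slope)
            + np.outer(zq, quad)
            + config.sex_effect * sex[:, None]
            + config.noise_sd * rng.standard_normal((n, config.n_rois))
        )
        return s

    loc_t, sc_t = _SCALES["thickness"]
    thick_vals = np.clip(
        loc_t + sc_t * gm_block(b_gm, quad_gm, -_LATENT_AMPLITUDE), 0.1, None
    )
    loc_a, sc_a = _SCALES["area"]
    area_vals = np.clip(loc_a + sc_a * gm_block(0.5 * b_gm, 0.0 * quad_gm, 0.0),
                        1.0, None)

    thickness = ROIMeasureTable("thickness", cohort.participant_id, regions,
                                thick_vals)
    area = ROIMeasureTable("area", cohort.participant_id, regions, area_vals)
    volume = ROIMeasureTable("volume", cohort.participant_id, regions,
                             thick_vals * area_vals)

    # --- white matter -----------------------------------------------------
    dims = tuple(config.grid_dims)
    if config.wm_effect_field is None:
        grad = (
            effect_field(dims, "posterior-anterior", 1.0)
            + effect_field(dims, "inferior-superior", 1.0)
        )
        field3d = 0.3 + grad / grad.max()  # strictly positive, gradient-shaped
    else:
        field3d = np.abs(config.wm_effect_field.copy())

    n_vox = int(np.prod(dims))
    n_null_vox = int(round(config.null_voxel_fraction * n_vox))
    null_vox_flat = rng.choice(n_vox, size=n_null_vox, replace=False)
    field_flat = field3d.ravel(order="C").copy()
    field_flat[null_vox_flat] = 0.0

    w_full = field_flat / (np.linalg.norm(field_flat) or 1.0)
    slope_wm = 0.3 * field_flat / (field_flat.max() or 1.0)
    quad_wm = np.zeros(n_vox)
    signal_vox = np.flatnonzero(field_flat)
    n_quad_v = int(round(config.quad_fraction * signal_vox.size))
    if n_quad_v:
        qv = rng.choice(signal_vox, size=n_quad_v, replace=False)
        quad_wm[qv] = 0.2 * field_flat[qv] / (field_flat.max() or 1.0)

    # amplitude per unit salience norm, spread over the voxel pattern
    a_w = _LATENT_AMPLITUDE * np.sqrt(signal_vox.size / max(config.n_rois, 1))

    def wm_signal(sign):
        return (
            sign * a_w * np.outer(latent, w_full)
            + sign * np.outer(z, slope_wm)
            + sign * np.outer(zq, quad_wm)
            + config.sex_effect * sex[:, None]
            + config.noise_sd * rng.standard_normal((n, n_vox))
        )

    base_fa = _base_fa_field(dims).ravel(order="C")
    sc_f = _SCALES["fa"][1]
    fa_flat = np.clip(base_fa[None, :] + sc_f * wm_signal(-1.0), 0.01, 0.99)
    loc_m, sc_m = _SCALES["md"]
    md_flat = np.clip(loc_m + sc_m * wm_signal(+1.0), 1e-5, None)

    fa_stack = fa_flat.reshape((n, *dims))
    template = build_template_mask(fa_stack, threshold=0.15)
    fa_matrix = vectorize(fa_stack, template, "FA", cohort.participant_id)
    md_matrix = vectorize(md_flat.reshape((n, *dims)), template, "MD",
                          cohort.participant_id)

    # restrict planted WM truth to the template and renormalize
    w_masked = w_full[template.voxel_order]
    nrm = np.linalg.norm(w_masked)
    w_masked = w_masked / nrm if nrm > 0 else w_masked

    flat_to_col = {f: c for c, f in enumerate(template.voxel_order)}
    null_ids = tuple(
        [str(regions[i]) for i in sorted(null_roi_idx)]
        + [f"voxel_{flat_to_col[f]:05d}" for f in sorted(null_vox_flat)
           if f in flat_to_col]
    )
    truth = PlantedTruth(
        true_gm_salience=u,
        true_wm_salience=w_masked,
        null_feature_ids=null_ids,
        latent_age_factor=latent0,
    )
    return thickness, area, volume, fa_matrix, md_matrix, template, truth


# ---------------------------------------------------------------------------
# white-matter hyperintensities
# ---------------------------------------------------------------------------


def inject_wmh(
    voxel_block: VoxelMetricMatrix, rate: float, seed: int
) -> WMHMask:
    """Flag Poisson-distributed random voxel subsets per participant.

    ``rate`` is the expected lesioned-voxel count per participant;
    placement is uniform without replacement over the template.
    """
    if rate < 0:
        raise ConfigurationError("rate must be >= 0")
    n_vox = voxel_block.template.n_voxels
    if rate > n_vox:
        raise ConfigurationError(f"rate {rate} exceeds template size {n_vox}")
    rng = np.random.default_rng([int(seed), 2])
    flags = {}
    for pid in voxel_block.participants:
        k = min(int(rng.poisson(rate)), n_vox)
        flags[pid] = rng.choice(n_vox, size=k, replace=False) if k else np.empty(0, int)
    return WMHMask(flags=flags, n_voxels=n_vox)


__all__ = [
    "DEFAULT_STRATA",
    "AXIS_DIRECTIONS",
    "ConfigurationError",
    "SimulationConfig",
    "PlantedTruth",
    "null_config",
    "generate_cohort",
    "generate_coupled_dataset",
    "effect_field",
    "inject_wmh",
]
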