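"""Block preparation for the two-block decomposition.

The PLSC recipe operates on two participants x features matrices, X
(white matter, voxelwise) and Y (gray matter, regional).  Preparation
is ordered and logged: optional WMH-voxel exclusion, residualization of
the sex covariate, then column centering and normalization to unit sum
of squares — after which cross-products of paired columns are Pearson
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
import warnings

import numpy as np

from structcov.data_io import (
    DataModelError,
    TemplateMask,
    VoxelMetricMatrix,
    WMHMask,
    subset_template,
)

_STEP_ORDER = ("exclude_wmh", "residualize", "center_normalize")


class PreprocessError(ValueError):
    pass


@dataclass
class PreprocessedBlock:
    """One data block with its ordered transform log.

    ``block_role`` is "X" for the white-matter (voxel) block and "Y"
    for the gray-matter (region) block.  After ``center_normalize``
    every column has mean 0 and sum of squares 1.
    """

    block_role: str
    values: np.ndarray
    feature_ids: np.ndarray
    participants: np.ndarray
    transform_log: tuple = ()

    def __post_init__(self) -> None:
        if self.block_role not in ("X", "Y"):
            raise PreprocessError("block_role must be 'X' or 'Y'")
        self.values = np.asarray(self.values, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.participants = np.asarray(self.participants, dtype=object)
        if self.values.shape != (len(self.participants), len(self.feature_ids)):
            raise PreprocessError("values shape mismatch")

    @property
    def is_normalized(self) -> bool:
        return "center_normalize" in self.transform_log

    def _check_step(self, step: str) -> None:
        if step in self.transform_log:
            raise PreprocessError(f"step {step!r} already applied")
        later = _STEP_ORDER.index(step)
        for done in self.transform_log:
            if _STEP_ORDER.index(done) > later:
                raise PreprocessError(
                    f"step {step!r} must precede {done!r} "
                    f"(pipeline order: {' -> '.join(_STEP_ORDER)})"
                )


def block_from_roi_table(table) -> PreprocessedBlock:
    """Wrap a gray-matter :class:`ROIMeasureTable` as the Y block."""
    return PreprocessedBlock(
        block_role="Y",
        values=table.values.copy(),
        feature_ids=table.regions.copy(),
        participants=table.participants.copy(),
    )


def block_from_voxel_matrix(matrix: VoxelMetricMatrix) -> PreprocessedBlock:
    """Wrap a white-matter :class:`VoxelMetricMatrix` as the X block."""
    ids = np.asarray(
        [f"voxel_{c:05d}" for c in range(matrix.template.n_voxels)], dtype=object
    )
    return PreprocessedBlock(
        block_role="X",
        values=matrix.values.copy(),
        feature_ids=ids,
        participants=matrix.participants.copy(),
    )


def residualize_covariate(
    block: PreprocessedBlock, covariate: np.ndarray
) -> PreprocessedBlock:
    """Replace each column by its residual from OLS on [intercept, covariate].

    The covariate (typically binary sex) is removed from every feature
    before the correlation structure is analyzed; residual columns are
    exactly uncorrelated with it.  A constant covariate degrades to
    intercept-only residualization (mean removal) with a warning.
    """
    block._check_step("residualize")
    cov = np.asarray(covariate, dtype=float)
    if cov.shape != (block.values.shape[0],):
        raise PreprocessError("covariate length must equal participant count")
    if np.ptp(cov) == 0:
        warnings.warn(
            "constant covariate: falling back to intercept-only residualization",
            stacklevel=2,
        )
        design = np.ones((len(cov), 1))
    else:
        design = np.column_stack([np.ones_like(cov), cov])
    beta, *_ = np.linalg.lstsq(design, block.values, rcond=None)
    resid = block.values - design @ beta
    return replace(
        block,
        values=resid,
        transform_log=block.transform_log + ("residualize",),
    )


def center_normalize(block: PreprocessedBlock) -> PreprocessedBlock:
    """Center each column and scale it to unit sum of squares.

    After this step X^T Y entries are Pearson correlations between the
    paired columns.  Constant columns cannot be normalized and raise an
    error naming the feature.
    """
    block._check_step("center_normalize")
    centered = block.values - block.values.mean(axis=0, keepdims=True)
    ss = np.sqrt(np.sum(centered**2, axis=0))
    bad = np.flatnonzero(ss == 0)
    if bad.size:
        raise PreprocessError(
            f"constant column(s) cannot be normalized: "
            f"{list(block.feature_ids[bad[:5]])}"
        )
    return replace(
        block,
        values=centered / ss,
        transform_log=block.transform_log + ("center_normalize",),
    )


def exclude_wmh_voxels(
    matrix: VoxelMetricMatrix, wmh: WMHMask
) -> tuple[VoxelMetricMatrix, TemplateMask]:
    """Drop every column flagged as WMH by *any* participant.

    The ultra-conservative union rule: a voxel lesioned in one
    participant is removed for all, so every retained column has clean
    data everywhere.  Returns the reduced matrix and a template
    consistent with the remaining columns.
    """
    if wmh.n_voxels != matrix.template.n_voxels:
        raise PreprocessError("WMH mask does not match matrix template")
    removed = wmh.union()
    keep = np.setdiff1d(np.arange(matrix.template.n_voxels), removed)
    new_template = subset_template(matrix.template, keep)
    return (
        VoxelMetricMatrix(
            metric=matrix.metric,
            participants=matrix.participants,
            template=new_template,
            values=matrix.values[:, keep],
        ),
        new_template,
    )


def prepare_blocks(
    x_block: PreprocessedBlock,
    y_block: PreprocessedBlock,
    sex: np.ndarray,
) -> tuple[PreprocessedBlock, PreprocessedBlock]:
    """Standard preparation of both blocks: residualize sex, then normalize."""
    if not np.array_equal(x_block.participants, y_block.participants):
        raise PreprocessError("blocks have different participant order")
    xb = center_normalize(residualize_covariate(x_block, sex))
    yb = center_normalize(residualize_covariate(y_block, sex))
    return xb, yb


__all__ = [
    "PreprocessError",
    "PreprocessedBlock",
    "block_from_roi_table",
    "block_from_voxel_matrix",
    "residualize_covariate",
    "center_normalize",
    "exclude_wmh_voxels",
    "prepare_blocks",
]
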