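"""Shared data model and file formats.

Containers tie the three kinds of data together: a cohort table
(participants with age and sex), regional morphometry tables
(participants x Desikan regions, one table per measure), and voxelwise
diffusion-metric matrices (participants x masked voxels) bound to a 3D
template grid.

Conventions (single-sourced here, recorded in every JSON sidecar):

* Grid axes are RAS-like: x = left->right, y = posterior->anterior,
  z = inferior->superior.  Arrays are indexed ``[x, y, z]``.
* Voxel linearization is row-major (C order) over ``(x, y, z)``: the
  flat index of voxel ``(i, j, k)`` on an ``(nx, ny, nz)`` grid is
  ``i*ny*nz + j*nz + k``, and masked-voxel columns follow ascending
  flat index.
* Tables are tab-separated UTF-8 with a header row; volumes are
  NIfTI-1, with participants along the 4th axis in cohort order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

AXIS_CONVENTION = {
    "x": "left->right (medial-lateral about the mid-sagittal plane)",
    "y": "posterior->anterior",
    "z": "inferior->superior",
}

ROI_MEASURES = ("thickness", "area", "volume")

#: Desikan-Killiany cortical parcellation, 34 regions per hemisphere.
DESIKAN_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal", "insula", "frontalpole",
)


class DataModelError(ValueError):
    """Invariant violation in one of the shared containers."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class CohortTable:
    """Participants with age (years) and sex (binary {0, 1} code).

    ``group_label`` is an optional display-only stratification; all
    models treat age as continuous.
    """

    participant_id: np.ndarray
    age: np.ndarray
    sex: np.ndarray
    group_label: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.participant_id = np.asarray(self.participant_id, dtype=object)
        self.age = np.asarray(self.age, dtype=float)
        self.sex = np.asarray(self.sex, dtype=int)
        n = len(self.participant_id)
        if len(self.age) != n or len(self.sex) != n:
            raise DataModelError("cohort columns have mismatched lengths")
        if len(set(self.participant_id)) != n:
            raise DataModelError("participant_ids are not unique")
        if not np.all(np.isfinite(self.age)) or np.any(self.age <= 0):
            raise DataModelError("ages must be finite and > 0")
        if not np.all(np.isin(self.sex, (0, 1))):
            raise DataModelError("sex must be coded {0, 1}")
        if self.group_label is not None:
            self.group_label = np.asarray(self.group_label, dtype=object)
            if len(self.group_label) != n:
                raise DataModelError("group_label length mismatch")

    @property
    def n(self) -> int:
        return len(self.participant_id)

    def to_frame(self) -> pd.DataFrame:
        d = {"participant_id": self.participant_id, "age": self.age, "sex": self.sex}
        if self.group_label is not None:
            d["group_label"] = self.group_label
        return pd.DataFrame(d)


@dataclass
class ROIMeasureTable:
    """Participants x regions matrix for one morphometry measure.

    Thickness is in mm, surface area in mm^2, volume in mm^3; all
    values must be finite and strictly positive.  Row order matches the
    cohort the table was built from.
    """

    measure: str
    participants: np.ndarray
    regions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.measure not in ROI_MEASURES:
            raise DataModelError(f"unknown measure {self.measure!r}")
        self.participants = np.asarray(self.participants, dtype=object)
        self.regions = np.asarray(self.regions, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.participants), len(self.regions)):
            raise DataModelError("values shape does not match participants x regions")
        if len(set(self.regions)) != len(self.regions):
            raise DataModelError("duplicate region names")
        if not np.all(np.isfinite(self.values)):
            raise DataModelError(f"{self.measure} table contains non-finite values")
        if np.any(self.values <= 0):
            i, j = np.argwhere(self.values <= 0)[0]
            raise DataModelError(
                f"{self.measure} must be strictly positive; offending cell "
                f"({self.participants[i]}, {self.regions[j]})"
            )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.regions))
        df.insert(0, "participant_id", self.participants)
        return df


@dataclass
class TemplateMask:
    """Boolean 3D template with a stable linearization of its voxels.

    ``voxel_order`` lists the flat (C-order over x,y,z) indices of the
    True voxels in ascending order; matrix columns follow it.
    """

    grid_dims: tuple[int, int, int]
    mask: np.ndarray
    fa_threshold: float = 0.15
    voxel_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.grid_dims = tuple(int(d) for d in self.grid_dims)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid_dims:
            raise DataModelError("mask shape does not match grid_dims")
        order = np.flatnonzero(self.mask.ravel(order="C"))
        if self.voxel_order is None:
            self.voxel_order = order
        else:
            self.voxel_order = np.asarray(self.voxel_order)
            if not np.array_equal(np.sort(self.voxel_order), order):
                raise DataModelError("voxel_order inconsistent with mask")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def sidecar(self) -> dict:
        return {
            "grid_dims": list(self.grid_dims),
            "fa_threshold": self.fa_threshold,
            "voxel_order": "C-order (row-major) flat index over (x, y, z)",
            "axis_convention": AXIS_CONVENTION,
            "n_voxels": self.n_voxels,
        }


@dataclass
class VoxelMetricMatrix:
    """Participants x masked-voxels matrix for one diffusion metric.

    FA is unitless in [0, 1]; MD is in mm^2/s and strictly positive.
    """

    metric: str
    participants: np.ndarray
    template: TemplateMask
    values: np.ndarray

    def __post_init__(self) -> None:
        if self.metric not in ("FA", "MD"):
            raise DataModelError(f"unknown metric {self.metric!r}")
        self.participants = np.asarray(self.participants, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.participants), self.template.n_voxels):
            raise DataModelError(
                "values shape does not match participants x template voxels"
            )
        if self.metric == "FA" and (
            np.any(self.values < 0) or np.any(self.values > 1)
        ):
            raise DataModelError("FA values must lie in [0, 1]")
        if self.metric == "MD" and np.any(self.values <= 0):
            raise DataModelError("MD values must be strictly positive")


@dataclass
class WMHMask:
    """Per-participant sets of flagged masked-voxel indices (WMH lesions)."""

    flags: dict
    n_voxels: int

    def __post_init__(self) -> None:
        clean = {}
        for pid, idx in self.flags.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_voxels):
                raise DataModelError(f"WMH index out of range for {pid}")
            clean[pid] = np.unique(idx)
        self.flags = clean

    def union(self) -> np.ndarray:
        """Column indices flagged by at least one participant."""
        if not self.flags:
            return np.empty(0, dtype=int)
        return np.unique(np.concatenate([v for v in self.flags.values()] or [[]]))


# ---------------------------------------------------------------------------
# cohort & ROI tables (TSV)
# ---------------------------------------------------------------------------


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.to_frame().to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> CohortTable:
    df = pd.read_csv(path, sep="\t")
    for col in ("participant_id", "age", "sex"):
        if col not in df.columns:
            raise DataModelError(f"cohort file missing column {col!r}")
    if df[["age", "sex"]].isna().any().any():
        raise DataModelError("cohort file has missing age/sex values")
    group = df["group_label"].to_numpy() if "group_label" in df.columns else None
    return CohortTable(
        participant_id=df["participant_id"].astype(str).to_numpy(),
        age=df["age"].to_numpy(),
        sex=df["sex"].to_numpy(),
        group_label=group,
    )


def write_roi_table(table: ROIMeasureTable, path: str | Path) -> None:
    """Write a region table as TSV (participant_id + one column per region)."""
    table.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_roi_table(path: str | Path, measure: str) -> ROIMeasureTable:
    """Read a TSV region table, preserving participant and region order.

    Raises a parse error naming the offending cell for missing ids,
    non-numeric entries or duplicate region columns.
    """
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    raw_regions = [c for c in header if c != "participant_id"]
    if len(set(raw_regions)) != len(raw_regions):
        dupes = sorted({r for r in raw_regions if raw_regions.count(r) > 1})
        raise DataModelError(f"duplicate region columns: {dupes}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "participant_id" not in df.columns:
        raise DataModelError("missing participant_id column")
    regions = [c for c in df.columns if c != "participant_id"]
    pids = df["participant_id"]
    if pids.isna().any():
        raise DataModelError(f"missing participant_id in row {int(pids.isna().idxmax())}")
    values = np.empty((len(df), len(regions)))
    for j, r in enumerate(regions):
        col = pd.to_numeric(df[r], errors="coerce")
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise DataModelError(
                f"non-numeric cell at (participant {pids.iloc[i]}, region {r})"
            )
        values[:, j] = col.to_numpy()
    return ROIMeasureTable(
        measure=measure,
        participants=pids.to_numpy(),
        regions=np.asarray(regions, dtype=object),
        values=values,
    )


# ---------------------------------------------------------------------------
# NIfTI volumes
# ---------------------------------------------------------------------------


def write_volume_stack(volumes: np.ndarray, path: str | Path) -> None:
    """Write per-participant 3D volumes as a 4D NIfTI (4th axis = participants)."""
    arr = np.asarray(volumes, dtype=np.float64)
    if arr.ndim != 4:
        raise DataModelError("expected participants x nx x ny x nz array")
    img = nib.Nifti1Image(np.moveaxis(arr, 0, -1), affine=np.eye(4))
    nib.save(img, str(path))


def read_volume_stack(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4:
        raise DataModelError("expected a 4D NIfTI stack")
    return np.moveaxis(data, -1, 0)


def write_mask(template: TemplateMask, path: str | Path, sidecar: bool = True) -> None:
    img = nib.Nifti1Image(template.mask.astype(np.uint8), affine=np.eye(4))
    nib.save(img, str(path))
    if sidecar:
        side = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii[.gz]
        Path(f"{side}.json").write_text(json.dumps(template.sidecar(), indent=2))


def read_mask(path: str | Path, fa_threshold: float = 0.15) -> TemplateMask:
    img = nib.load(str(path))
    mask = np.asarray(img.dataobj) > 0
    return TemplateMask(grid_dims=mask.shape, mask=mask, fa_threshold=fa_threshold)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def build_template_mask(
    fa_stack: np.ndarray, threshold: float = 0.15
) -> TemplateMask:
    """Study-template rule: keep a voxel iff FA > threshold in *every* participant.

    The comparison is strict; a voxel with FA exactly at the threshold
    in any participant is excluded.  An empty mask is permitted (the
    caller is warned) so the rule stays total.
    """
    arr = np.asarray(fa_stack, dtype=float)
    if arr.ndim != 4:
        raise DataModelError("fa_stack must be participants x nx x ny x nz")
    mask = np.all(arr > threshold, axis=0)
    if not mask.any():
        import warnings

        warnings.warn("template mask is empty at this threshold", stacklevel=2)
    return TemplateMask(grid_dims=mask.shape, mask=mask, fa_threshold=threshold)


def vectorize(
    volumes: np.ndarray,
    template: TemplateMask,
    metric: str,
    participants: np.ndarray,
) -> VoxelMetricMatrix:
    """Flatten per-participant 3D volumes into a participants x voxels matrix.

    Columns follow ``template.voxel_order`` (ascending C-order flat
    index); the function is pure in (mask, ordering).
    """
    arr = np.asarray(volumes, dtype=float)
    if arr.shape[1:] != template.grid_dims:
        raise DataModelError(
            f"volume grid {arr.shape[1:]} does not match template {template.grid_dims}"
        )
    flat = arr.reshape(arr.shape[0], -1)  # C order over (x, y, z)
    return VoxelMetricMatrix(
        metric=metric,
        participants=participants,
        template=template,
        values=flat[:, template.voxel_order],
    )


def devectorize(matrix: VoxelMetricMatrix, fill: float = 0.0) -> np.ndarray:
    """Inverse of :func:`vectorize`; outside-mask voxels get the sentinel ``fill``."""
    tpl = matrix.template
    n = matrix.values.shape[0]
    flat = np.full((n, int(np.prod(tpl.grid_dims))), fill, dtype=float)
    flat[:, tpl.voxel_order] = matrix.values
    return flat.reshape((n, *tpl.grid_dims))


def devectorize_map(
    values: np.ndarray, template: TemplateMask, fill: float = 0.0
) -> np.ndarray:
    """Scatter a per-voxel statistic vector back onto the 3D grid."""
    values = np.asarray(values, dtype=float)
    if values.shape != (template.n_voxels,):
        raise DataModelError("statistic length does not match template voxel count")
    flat = np.full(int(np.prod(template.grid_dims)), fill, dtype=float)
    flat[template.voxel_order] = values
    return flat.reshape(template.grid_dims)


def average_hemispheres(table: ROIMeasureTable) -> ROIMeasureTable:
    """Average lh_/rh_ qualified region pairs within each participant.

    Returns a table with unqualified region names; any region missing
    its partner is an error listing the orphans.
    """
    lh = {r[3:]: j for j, r in enumerate(table.regions) if str(r).startswith("lh_")}
    rh = {r[3:]: j for j, r in enumerate(table.regions) if str(r).startswith("rh_")}
    unqualified = [
        r for r in table.regions
        if not (str(r).startswith("lh_") or str(r).startswith("rh_"))
    ]
    if unqualified:
        raise DataModelError(f"regions without hemisphere qualifier: {unqualified}")
    orphans = sorted(set(lh) ^ set(rh))
    if orphans:
        raise DataModelError(f"regions missing a hemisphere partner: {orphans}")
    names = [r[3:] for r in table.regions if str(r).startswith("lh_")]
    values = np.column_stack(
        [(table.values[:, lh[n]] + table.values[:, rh[n]]) / 2.0 for n in names]
    )
    return ROIMeasureTable(
        measure=table.measure,
        participants=table.participants,
        regions=np.asarray(names, dtype=object),
        values=values,
    )


def wmh_burden(wmh: WMHMask, template: TemplateMask) -> pd.Series:
    """Per-participant WMH burden as a percentage of template voxels."""
    if wmh.n_voxels != template.n_voxels:
        raise DataModelError("WMH mask and template voxel counts differ")
    total = template.n_voxels
    return pd.Series(
        {pid: 100.0 * len(idx) / total for pid, idx in wmh.flags.items()},
        dtype=float,
    )


def subset_template(template: TemplateMask, keep_cols: np.ndarray) -> TemplateMask:
    """Template restricted to a subset of its current columns (by column index)."""
    new_mask = np.zeros(template.grid_dims, dtype=bool).ravel()
    new_mask[template.voxel_order[keep_cols]] = True
    return TemplateMask(
        grid_dims=template.grid_dims,
        mask=new_mask.reshape(template.grid_dims),
        fa_threshold=template.fa_threshold,
    )


__all__ = [
    "AXIS_CONVENTION",
    "DESIKAN_REGIONS",
    "ROI_MEASURES",
    "DataModelError",
    "CohortTable",
    "ROIMeasureTable",
    "TemplateMask",
    "VoxelMetricMatrix",
    "WMHMask",
    "read_cohort",
    "write_cohort",
    "read_roi_table",
    "write_roi_table",
    "read_volume_stack",
    "write_volume_stack",
    "read_mask",
    "write_mask",
    "build_template_mask",
    "vectorize",
    "devectorize",
    "devectorize_map",
    "average_hemispheres",
    "wmh_burden",
    "subset_template",
]
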