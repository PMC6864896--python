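"""Shared setup for the numbered analysis drivers.

Every driver regenerates the same synthetic study deterministically
from STUDY_SEED, so the scripts can run independently and in any
order; all outputs land under results/analysis/.
"""

from pathlib import Path

from structcov.preprocess import (
    block_from_roi_table,
    block_from_voxel_matrix,
    prepare_blocks,
)
from structcov.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_coupled_dataset,
)

STUDY_SEED = 11
RESULTS = Path("results/analysis")


def study_config() -> SimulationConfig:
    """The default study conditions: 186 participants, ages 20-94 in
    four strata, 34 ROIs, 10x12x10 grid, coupling 0.9."""
    return SimulationConfig(seed=STUDY_SEED)


def study_dataset():
    cfg = study_config()
    cohort = generate_cohort(cfg)
    thickness, area, volume, fa, md, template, truth = generate_coupled_dataset(
        cfg, cohort
    )
    return {
        "config": cfg,
        "cohort": cohort,
        "thickness": thickness,
        "area": area,
        "volume": volume,
        "fa": fa,
        "md": md,
        "template": template,
        "truth": truth,
    }


def study_blocks(data, metric="FA"):
    wm = data["fa"] if metric == "FA" else data["md"]
    return prepare_blocks(
        block_from_voxel_matrix(wm),
        block_from_roi_table(data["thickness"]),
        data["cohort"].sex,
    )


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
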