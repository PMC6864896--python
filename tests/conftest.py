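import numpy as np
import pytest

from structcov.plsc import plsc_fit
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


@pytest.fixture(scope="session")
def coupled():
    """Full-scale coupled dataset at the default study conditions.

    186 participants in four age strata, 34 ROIs, 10x12x10 grid,
    coupling 0.9; shared across recovery and acceptance tests.
    """
    cfg = SimulationConfig(seed=11)
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


@pytest.fixture(scope="session")
def coupled_blocks(coupled):
    xb, yb = prepare_blocks(
        block_from_voxel_matrix(coupled["fa"]),
        block_from_roi_table(coupled["thickness"]),
        coupled["cohort"].sex,
    )
    return xb, yb


@pytest.fixture(scope="session")
def coupled_model(coupled_blocks):
    return plsc_fit(*coupled_blocks)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_noise_blocks(rng, n=30, p=6, q=4):
    """Independent pure-noise blocks, fully preprocessed."""
    from structcov.preprocess import PreprocessedBlock, center_normalize

    pids = np.array([f"s{i}" for i in range(n)], dtype=object)
    xb = center_normalize(
        PreprocessedBlock(
            "X", rng.standard_normal((n, p)),
            np.array([f"x{j}" for j in range(p)], dtype=object), pids,
        )
    )
    yb = center_normalize(
        PreprocessedBlock(
            "Y", rng.standard_normal((n, q)),
            np.array([f"y{j}" for j in range(q)], dtype=object), pids,
        )
    )
    return xb, yb
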