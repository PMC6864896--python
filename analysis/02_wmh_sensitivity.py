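"""WMH sensitivity analysis: does excluding lesioned voxels change PLSC?

Mirrors the study's robustness check — every voxel flagged as a white
matter hyperintensity in any participant is removed for all
participants, and the component-1 summary is compared with the
WMH-inclusive analysis.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import outdir, study_dataset

import numpy as np
import pandas as pd

from structcov.data_io import wmh_burden
from structcov.plsc import plsc_fit
from structcov.preprocess import (
    block_from_roi_table,
    block_from_voxel_matrix,
    exclude_wmh_voxels,
    prepare_blocks,
)
from structcov.simulate import inject_wmh


def fit_summary(fa, thickness, sex):
    xb, yb = prepare_blocks(
        block_from_voxel_matrix(fa), block_from_roi_table(thickness), sex
    )
    m = plsc_fit(xb, yb)
    return m, xb, yb


def main():
    out = outdir("wmh_sensitivity")
    data = study_dataset()
    cohort, fa = data["cohort"], data["fa"]
    wmh = inject_wmh(fa, data["config"].wmh_rate, seed=data["config"].seed)

    burden = wmh_burden(wmh, fa.template)
    m_incl, *_ = fit_summary(fa, data["thickness"], cohort.sex)
    fa_excl, _ = exclude_wmh_voxels(fa, wmh)
    m_excl, *_ = fit_summary(fa_excl, data["thickness"], cohort.sex)

    gm_r = np.corrcoef(m_incl.V[:, 0], m_excl.V[:, 0])[0, 1]
    rows = pd.DataFrame(
        {
            "analysis": ["wmh_included", "wmh_excluded"],
            "n_voxels": [fa.template.n_voxels, fa_excl.template.n_voxels],
            "var_explained_c1": [m_incl.var_explained[0],
                                 m_excl.var_explained[0]],
            "delta_1": [m_incl.delta[0], m_excl.delta[0]],
        }
    )
    rows.to_csv(out / "sensitivity.tsv", sep="\t", index=False)

    print(f"median WMH burden: {burden.median():.3f}% of template voxels")
    print(rows.to_string(index=False))
    print(f"GM salience agreement (included vs excluded): r = {gm_r:.4f}")
    verdict = "no material difference" if abs(gm_r) > 0.99 else "diverges"
    print(f"conclusion: {verdict}; the WMH-inclusive analysis is reported")


if __name__ == "__main__":
    main()
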