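"""Generate the synthetic lifespan cohort and coupled GM/WM dataset.

Writes the cohort table, the demographic summary, the three regional
morphometry tables and the planted ground truth; prints what the
study design looks like.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import outdir, study_dataset

import numpy as np
import pandas as pd

from structcov.data_io import write_cohort, write_mask, write_roi_table
from structcov.pipeline import summarize_cohort
from structcov.simulate import inject_wmh


def main():
    out = outdir("data")
    data = study_dataset()
    cohort = data["cohort"]

    write_cohort(cohort, out / "cohort.tsv")
    summary = summarize_cohort(cohort)
    summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
    for m in ("thickness", "area", "volume"):
        write_roi_table(data[m], out / f"gm_{m}.tsv")
    write_mask(data["template"], out / "template_mask.nii.gz")

    truth = data["truth"]
    pd.DataFrame(
        {"region": data["thickness"].regions,
         "true_salience": truth.true_gm_salience}
    ).to_csv(out / "planted_gm_salience.tsv", sep="\t", index=False)
    (out / "planted_truth.json").write_text(json.dumps(
        {"null_feature_ids": list(truth.null_feature_ids),
         "n_template_voxels": data["template"].n_voxels}, indent=2))

    wmh = inject_wmh(data["fa"], data["config"].wmh_rate, seed=data["config"].seed)
    burden = [len(v) for v in wmh.flags.values()]

    print(f"cohort: n={cohort.n}, ages {cohort.age.min():.1f}-"
          f"{cohort.age.max():.1f}, {int((cohort.sex == 1).sum())} female")
    print(summary.to_string(index=False))
    print(f"template: {data['template'].n_voxels} of "
          f"{int(np.prod(data['template'].grid_dims))} voxels retained "
          f"(FA > 0.15 in every participant)")
    print(f"WMH: mean {np.mean(burden):.1f} lesioned voxels per participant")
    print(f"wrote tables to {out}")


if __name__ == "__main__":
    main()
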