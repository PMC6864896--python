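"""Spatial age-gradient profiles of the white-matter metrics.

Computes the per-voxel age correlation for FA and MD and summarizes
its magnitude slice by slice along the posterior-anterior,
inferior-superior and medial-lateral axes, testing the planted
anterior/superior gradients for a monotone trend.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from _common import outdir, study_dataset

import numpy as np
import pandas as pd
from scipy import stats

from structcov.univariate import age_correlation_map, gradient_profile

AXES = ("posterior-anterior", "inferior-superior", "medial-lateral")


def main():
    out = outdir("gradients")
    data = study_dataset()
    age = data["cohort"].age

    for metric in ("FA", "MD"):
        matrix = data["fa"] if metric == "FA" else data["md"]
        r_map = age_correlation_map(matrix, age)
        print(f"{metric}: mean |r(age)| over template = "
              f"{np.mean(np.abs(r_map)):.3f}")
        for axis in AXES:
            prof = gradient_profile(r_map, matrix.template, axis)
            pd.DataFrame({
                "slice": prof.slice_index, "mean_abs_r": prof.statistic,
                "n_voxels": prof.n_voxels,
            }).to_csv(out / f"{metric}_{axis}.tsv", sep="\t", index=False)
            good = np.isfinite(prof.statistic) & (prof.n_voxels >= 20)
            rho = stats.spearmanr(
                prof.slice_index[good], prof.statistic[good]
            ).statistic
            print(f"  {axis}: trend Spearman rho = {rho:+.2f} "
                  f"over {int(good.sum())} well-filled slices")
    print("planted gradients run anteriorly and superiorly; the "
          "medial-lateral profile has no planted trend")
    print(f"wrote tables to {out}")


if __name__ == "__main__":
    main()
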