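"""Pipeline orchestration: simulate/ingest -> preprocess -> univariate ->
PLSC -> inference -> report.

Each stage is a plain function over the shared containers so the
numbered analysis drivers, the tests and the acceptance script can run
any slice of the pipeline; :func:`run_pipeline` composes them under a
single :class:`RunConfig`, logs every stage with parameter and output
checksums, and writes artifacts into a fixed run-directory layout
(``tables/``, ``maps/``, ``model/``, ``report/``).  All randomness
derives from ``config.seed``; rerunning an identical config reproduces
every numeric output bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from structcov import data_io
from structcov.data_io import CohortTable
from structcov.inference import (
    bootstrap_bsr,
    permutation_test_components,
    regress_scores_on_age,
    threshold_bsr,
)
from structcov.plsc import plsc_fit
from structcov.preprocess import (
    block_from_roi_table,
    block_from_voxel_matrix,
    exclude_wmh_voxels,
    prepare_blocks,
)
from structcov.simulate import (
    SimulationConfig,
    generate_cohort,
    generate_coupled_dataset,
    inject_wmh,
)
from structcov.univariate import (
    age_correlation_map,
    fit_age_model,
    fwe_maxstat_pvalues,
    gradient_profile,
)

#: Display-only age-group edges for cohort summaries (years).
DEFAULT_GROUP_EDGES = (20, 35, 55, 70, 95)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Exactly one input source: a :class:`SimulationConfig` (synthetic
    run) or paths to a cohort TSV, ROI tables and NIfTI stacks.
    """

    simulation: SimulationConfig | None = None
    input_paths: dict | None = None
    out_dir: str = "results/run"
    seed: int = 0
    n_perm: int = 500
    n_boot: int = 500
    n_perm_univariate: int = 200
    alpha: float = 0.05
    bsr_cutoff: float = 3.0
    fa_threshold: float = 0.15
    exclude_wmh: bool = False
    wm_metrics: tuple = ("FA", "MD")
    do_univariate: bool = True
    do_voxelwise_fwe: bool = False
    do_plsc: bool = True
    do_inference: bool = True

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.input_paths is None):
            raise ValueError(
                "exactly one of simulation config or input_paths must be given"
            )
        for name in ("n_perm", "n_boot", "n_perm_univariate"):
            if getattr(self, name) < 100:
                raise ValueError(f"{name} must be >= 100")

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.simulation is not None:
            d["simulation"] = {
                k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in asdict(self.simulation).items()
            }
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if "include" in raw:  # one include level
            base = yaml.safe_load(Path(raw.pop("include")).read_text())
            base.update(raw)
            raw = base
        sim = raw.pop("simulation", None)
        if sim is not None:
            for key in ("age_range", "grid_dims"):
                if key in sim:
                    sim[key] = tuple(sim[key])
            if "group_strata" in sim and sim["group_strata"] is not None:
                sim["group_strata"] = tuple(tuple(s) for s in sim["group_strata"])
            sim = SimulationConfig(**sim)
        if "wm_metrics" in raw:
            raw["wm_metrics"] = tuple(raw["wm_metrics"])
        return cls(simulation=sim, **raw)


def _checksum(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


@dataclass
class ReportBundle:
    """All numeric artifacts of a run plus provenance.

    Report rendering only reads from this bundle; numbers are computed
    once by their stage and never recomputed at render time.
    """

    config: RunConfig
    cohort_summary: pd.DataFrame | None = None
    univariate_roi: pd.DataFrame | None = None
    gradient_profiles: dict = field(default_factory=dict)
    fwe_maps: dict = field(default_factory=dict)
    plsc: dict = field(default_factory=dict)
    inference: dict = field(default_factory=dict)
    stage_log: list = field(default_factory=list)

    def log(self, stage: str, params: dict, checksum: str) -> None:
        self.stage_log.append(
            {"stage": stage, "params": params, "checksum": checksum}
        )


# ---------------------------------------------------------------------------
# cohort summary
# ---------------------------------------------------------------------------


def pooled_mean(sizes, means) -> float:
    """Size-weighted mean of group means (the pooled grand mean)."""
    sizes = np.asarray(sizes, dtype=float)
    means = np.asarray(means, dtype=float)
    return float(np.sum(sizes * means) / np.sum(sizes))


def summarize_cohort(
    cohort: CohortTable,
    group_edges=DEFAULT_GROUP_EDGES,
    extra: dict | None = None,
) -> pd.DataFrame:
    """Demographic summary by (display-only) age group plus a pooled row.

    Per group: n, sex split, mean and SD of age and of any extra
    numeric covariates; the pooled mean is computed as the size-weighted
    mean of the group means.  Empty groups are reported with n = 0.
    """
    edges = list(group_edges)
    if any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("group edges must be strictly increasing")
    extra = extra or {}
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (cohort.age >= lo) & (cohort.age < hi)
        row = {
            "group": f"{lo}-{hi - 1}",
            "n": int(sel.sum()),
            "n_male": int(np.sum(cohort.sex[sel] == 0)),
            "n_female": int(np.sum(cohort.sex[sel] == 1)),
            "age_mean": float(cohort.age[sel].mean()) if sel.any() else np.nan,
            "age_sd": float(cohort.age[sel].std(ddof=1)) if sel.sum() > 1 else np.nan,
        }
        for name, vals in extra.items():
            v = np.asarray(vals, dtype=float)[sel]
            row[f"{name}_mean"] = float(v.mean()) if sel.any() else np.nan
            row[f"{name}_sd"] = float(v.std(ddof=1)) if sel.sum() > 1 else np.nan
        rows.append(row)
    df = pd.DataFrame(rows)
    filled = df[df["n"] > 0]
    pooled = {
        "group": "pooled",
        "n": int(df["n"].sum()),
        "n_male": int(df["n_male"].sum()),
        "n_female": int(df["n_female"].sum()),
        "age_mean": pooled_mean(filled["n"], filled["age_mean"]),
        "age_sd": float(cohort.age.std(ddof=1)),
    }
    for name, vals in extra.items():
        pooled[f"{name}_mean"] = pooled_mean(filled["n"], filled[f"{name}_mean"])
        pooled[f"{name}_sd"] = float(np.asarray(vals, dtype=float).std(ddof=1))
    return pd.concat([df, pd.DataFrame([pooled])], ignore_index=True)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_data(config: RunConfig):
    """Simulate (or ingest) the cohort, GM tables, WM matrices and WMH mask."""
    if config.simulation is not None:
        sim = config.simulation
        cohort = generate_cohort(sim)
        thickness, area, volume, fa, md, template, truth = generate_coupled_dataset(
            sim, cohort
        )
        wmh = (
            inject_wmh(fa, sim.wmh_rate, seed=sim.seed)
            if sim.wmh_rate > 0
            else None
        )
        return cohort, {"thickness": thickness, "area": area, "volume": volume}, \
            {"FA": fa, "MD": md}, template, wmh, truth
    paths = config.input_paths
    cohort = data_io.read_cohort(paths["cohort"])
    gm = {
        m: data_io.read_roi_table(paths[m], m)
        for m in ("thickness", "area", "volume")
        if m in paths
    }
    fa_stack = data_io.read_volume_stack(paths["fa"])
    template = data_io.build_template_mask(fa_stack, config.fa_threshold)
    wm = {"FA": data_io.vectorize(fa_stack, template, "FA", cohort.participant_id)}
    if "md" in paths:
        md_stack = data_io.read_volume_stack(paths["md"])
        wm["MD"] = data_io.vectorize(md_stack, template, "MD", cohort.participant_id)
    return cohort, gm, wm, template, None, None


def stage_preprocess(config: RunConfig, cohort, gm, wm, wmh):
    """Optional WMH exclusion, sex residualization, column normalization."""
    if config.exclude_wmh and wmh is not None:
        wm = {k: exclude_wmh_voxels(v, wmh)[0] for k, v in wm.items()}
    blocks = {}
    y_raw = block_from_roi_table(gm["thickness"])
    for metric in config.wm_metrics:
        x_raw = block_from_voxel_matrix(wm[metric])
        xb, yb = prepare_blocks(x_raw, y_raw, cohort.sex)
        blocks[metric] = (xb, yb)
    return blocks, wm


def stage_univariate(config: RunConfig, cohort, gm, wm, bundle: ReportBundle):
    """ROI age models, slice-wise gradient profiles, optional voxelwise FWE."""
    rows = []
    thick = gm["thickness"]
    for j, region in enumerate(thick.regions):
        res = fit_age_model(
            thick.values[:, j],
            cohort.age,
            cohort.sex,
            alpha=config.alpha,
            n_perm=config.n_perm_univariate,
            seed=config.seed + j,
            feature_id=str(region),
        )
        rows.append(
            {
                "region": res.feature_id,
                "model_form": res.model_form,
                "std_beta_age": res.std_beta_age,
                "t_age": res.t_age,
                "p_perm": res.p_perm,
                "std_beta_age2": res.std_beta_age2,
            }
        )
    bundle.univariate_roi = pd.DataFrame(rows)
    for metric, matrix in wm.items():
        r = age_correlation_map(matrix, cohort.age)
        bundle.gradient_profiles[metric] = {
            axis: gradient_profile(r, matrix.template, axis)
            for axis in ("posterior-anterior", "inferior-superior", "medial-lateral")
        }
        if config.do_voxelwise_fwe:
            bundle.fwe_maps[metric] = fwe_maxstat_pvalues(
                matrix,
                cohort.age,
                cohort.sex,
                B=config.n_perm_univariate,
                seed=config.seed,
            )
    bundle.log(
        "univariate",
        {"n_perm": config.n_perm_univariate, "alpha": config.alpha},
        _checksum(bundle.univariate_roi["t_age"].to_numpy()),
    )


def stage_plsc(config: RunConfig, blocks, bundle: ReportBundle):
    for metric, (xb, yb) in blocks.items():
        model = plsc_fit(xb, yb)
        bundle.plsc[metric] = model
        bundle.log(
            f"plsc_{metric}",
            {"n_components": model.n_components},
            _checksum(model.delta, model.V),
        )


def stage_inference(config: RunConfig, cohort, blocks, bundle: ReportBundle):
    for metric, (xb, yb) in blocks.items():
        model = bundle.plsc[metric]
        perm = permutation_test_components(
            xb, yb, n_perm=config.n_perm, seed=config.seed
        )
        boot = bootstrap_bsr(
            xb, yb, model, n_boot=config.n_boot, seed=config.seed
        )
        sig_x, sig_y = threshold_bsr(boot, cutoff=config.bsr_cutoff)
        fits = {
            "GM": regress_scores_on_age(model.Ly[:, 0], cohort.age, config.alpha),
            "WM": regress_scores_on_age(model.Lx[:, 0], cohort.age, config.alpha),
        }
        bundle.inference[metric] = {
            "permutation": perm,
            "bootstrap": boot,
            "sig_x": sig_x,
            "sig_y": sig_y,
            "score_age": fits,
        }
        bundle.log(
            f"inference_{metric}",
            {"n_perm": config.n_perm, "n_boot": config.n_boot,
             "bsr_cutoff": config.bsr_cutoff},
            _checksum(perm.p_per_component, boot.bsr_Y),
        )


# ---------------------------------------------------------------------------
# composition & artifact writing
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, write: bool = True) -> ReportBundle:
    """Execute all enabled stages and (optionally) write the run directory."""
    bundle = ReportBundle(config=config)
    cohort, gm, wm, template, wmh, truth = stage_data(config)
    bundle.cohort_summary = summarize_cohort(cohort)
    bundle.log(
        "data",
        {"source": "simulation" if config.simulation else "files",
         "n": cohort.n, "template_voxels": template.n_voxels},
        _checksum(cohort.age, gm["thickness"].values),
    )
    blocks, wm = stage_preprocess(config, cohort, gm, wm, wmh)
    if config.do_univariate:
        stage_univariate(config, cohort, gm, wm, bundle)
    if config.do_plsc:
        stage_plsc(config, blocks, bundle)
        if config.do_inference:
            stage_inference(config, cohort, blocks, bundle)
    if write:
        write_bundle(bundle, template, truth)
    return bundle


def write_bundle(bundle: ReportBundle, template, truth=None) -> Path:
    from structcov.report import render_report

    out = Path(bundle.config.out_dir)
    for sub in ("tables", "maps", "model", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    bundle.cohort_summary.to_csv(out / "tables" / "cohort_summary.tsv",
                                 sep="\t", index=False)
    if bundle.univariate_roi is not None:
        bundle.univariate_roi.to_csv(out / "tables" / "univariate_roi.tsv",
                                     sep="\t", index=False)
    for metric, profs in bundle.gradient_profiles.items():
        for axis, prof in profs.items():
            pd.DataFrame(
                {"slice": prof.slice_index, "statistic": prof.statistic,
                 "n_voxels": prof.n_voxels}
            ).to_csv(out / "tables" / f"gradient_{metric}_{axis}.tsv",
                     sep="\t", index=False)
    data_io.write_mask(template, out / "maps" / "template_mask.nii.gz")
    for metric, model in bundle.plsc.items():
        mdir = out / "model" / metric
        mdir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"delta": model.delta, "var_explained": model.var_explained}
        ).to_csv(mdir / "singular_values.tsv", sep="\t", index=False)
        pd.DataFrame(model.V, index=model.y_feature_ids).to_csv(
            mdir / "gm_saliences.tsv", sep="\t", header=False
        )
        scores = pd.DataFrame(
            {"participant_id": model.participants,
             "score_wm": model.Lx[:, 0], "score_gm": model.Ly[:, 0]}
        )
        scores.to_csv(mdir / "brain_scores.tsv", sep="\t", index=False)
        wm_sal = data_io.devectorize_map(model.U[:, 0], template)
        data_io.write_volume_stack(wm_sal[None], mdir / "wm_salience_c1.nii.gz")
    for metric, inf in bundle.inference.items():
        mdir = out / "model" / metric
        mdir.mkdir(parents=True, exist_ok=True)
        perm = inf["permutation"]
        pd.DataFrame(
            {"component": np.arange(1, len(perm.p_per_component) + 1),
             "delta": perm.observed_delta[: len(perm.p_per_component)],
             "p_perm": perm.p_per_component}
        ).to_csv(mdir / "permutation.tsv", sep="\t", index=False)
        boot = inf["bootstrap"]
        pd.DataFrame(
            {"region": bundle.plsc[metric].y_feature_ids,
             "bsr": boot.bsr_Y, "significant": inf["sig_y"]}
        ).to_csv(mdir / "gm_bsr.tsv", sep="\t", index=False)
        bsr_map = data_io.devectorize_map(boot.bsr_X, template)
        data_io.write_volume_stack(bsr_map[None], mdir / "wm_bsr_c1.nii.gz")
    provenance = {
        "config_hash": bundle.config.config_hash(),
        "seed": bundle.config.seed,
        "stage_log": bundle.stage_log,
    }
    (out / "report" / "provenance.json").write_text(
        json.dumps(provenance, indent=2, default=str)
    )
    (out / "report" / "summary.md").write_text(render_report(bundle))
    return out


__all__ = [
    "DEFAULT_GROUP_EDGES",
    "RunConfig",
    "ReportBundle",
    "pooled_mean",
    "summarize_cohort",
    "stage_data",
    "stage_preprocess",
    "stage_univariate",
    "stage_plsc",
    "stage_inference",
    "run_pipeline",
    "write_bundle",
]
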