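"""Human-readable run summary.

Renders a single markdown document from a :class:`~structcov.pipeline.
ReportBundle`: cohort demographics, significant univariate regions,
component permutation p-values and variance explained, BSR-significant
region/voxel counts, and the preferred form of each score-age model.
Rendering is read-only — every number comes from a stage artifact in
the bundle, never recomputed here.
"""

from __future__ import annotations

import numpy as np


def _fmt_p(p: float) -> str:
    return f"{p:.4g}"


def render_report(bundle) -> str:
    cfg = bundle.config
    lines = [
        "# Structural covariance run report",
        "",
        f"- config hash: `{cfg.config_hash()}`",
        f"- master seed: {cfg.seed}",
        f"- resampling: n_perm={cfg.n_perm}, n_boot={cfg.n_boot}, "
        f"alpha={cfg.alpha}, BSR cutoff={cfg.bsr_cutoff}",
        "",
        "## Cohort",
        "",
    ]
    if bundle.cohort_summary is not None:
        lines.append(bundle.cohort_summary.to_string(index=False))
    lines += ["", "## Univariate age effects (GM thickness)", ""]
    if bundle.univariate_roi is None:
        lines.append("not run")
    else:
        df = bundle.univariate_roi
        sig = df[df["p_perm"] < cfg.alpha]
        quad = df[df["model_form"] == "quadratic"]
        lines += [
            f"- {len(sig)}/{len(df)} regions with permutation p < {cfg.alpha}",
            f"- {len(quad)} regions better fitted with a quadratic age term",
        ]
        if len(sig):
            strongest = sig.iloc[np.argmax(np.abs(sig["std_beta_age"]))]
            lines.append(
                f"- strongest standardized age effect: {strongest['region']} "
                f"(beta = {strongest['std_beta_age']:.3f})"
            )
    for metric, profs in bundle.gradient_profiles.items():
        lines += ["", f"## Gradient profiles ({metric})", ""]
        for axis, prof in profs.items():
            vals = prof.statistic[np.isfinite(prof.statistic)]
            if vals.size:
                lines.append(
                    f"- {axis}: mean |r| from {vals[0]:.3f} (first slice) "
                    f"to {vals[-1]:.3f} (last slice)"
                )
    lines += ["", "## PLSC", ""]
    if not bundle.plsc:
        lines.append("not run")
    for metric, model in bundle.plsc.items():
        lines.append(
            f"- thickness-{metric}: component 1 explains "
            f"{100 * model.var_explained[0]:.2f}% of cross-block covariance "
            f"(delta_1 = {model.delta[0]:.3f}, K = {model.n_components})"
        )
    lines += ["", "## Inference", ""]
    if not bundle.inference:
        lines.append("not run")
    for metric, inf in bundle.inference.items():
        perm = inf["permutation"]
        n_sig = int(np.sum(perm.p_per_component < cfg.alpha))
        lines += [
            f"### thickness-{metric}",
            f"- components with permutation p < {cfg.alpha}: {n_sig} "
            f"(component 1 p = {_fmt_p(perm.p_per_component[0])})",
            f"- BSR-significant (|BSR| >= {cfg.bsr_cutoff}): "
            f"{int(inf['sig_y'].sum())}/{len(inf['sig_y'])} GM regions, "
            f"{int(inf['sig_x'].sum())}/{len(inf['sig_x'])} WM voxels",
        ]
        for block, fit in inf["score_age"].items():
            lines.append(
                f"- {block} score ~ age: preferred {fit.preferred} form "
                f"(linear F({fit.df_linear[0]},{fit.df_linear[1]}) = "
                f"{fit.f_linear:.1f}, p = {_fmt_p(fit.p_linear)}; "
                f"quadratic-term p = {_fmt_p(fit.p_quad_term)})"
            )
        lines.append("")
    return "\n".join(lines) + "\n"


__all__ = ["render_report"]
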