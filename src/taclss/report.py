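"""Human-readable markdown report over a completed pipeline run.

Reproduces the customary table shapes of an LSS study: a cohort summary, the
all-subsets model table with equations and adjusted r2, the validation table,
and the CYP3A5 section with one-decimal percentages. Floats are rounded for
display only; the CSVs keep full precision.
"""

from __future__ import annotations

import json
import os

import numpy as np
import pandas as pd

from .pharmacogenetics import round_half_away


def _section_cohort(outdir: str) -> list[str]:
    meta = pd.read_csv(os.path.join(outdir, "cohort_metadata.csv"))
    expo = pd.read_csv(os.path.join(outdir, "exposure_summary.csv"))
    tmax = expo["tmax"]
    lines = [
        "## Cohort summary",
        "",
        f"- patients: {len(meta)}",
        f"- TAC-D (mg/kg, mean ± SD): {meta['tac_d_mg_per_kg'].mean():.3f} ± {meta['tac_d_mg_per_kg'].std(ddof=1):.3f}",
        f"- trapezoidal AUC(0-24) (ng·h/mL, mean ± SD): {expo['auc_0_24'].mean():.0f} ± {expo['auc_0_24'].std(ddof=1):.0f}",
        f"- C0 (ng/mL, mean ± SD): {expo['c0'].mean():.1f} ± {expo['c0'].std(ddof=1):.1f}",
        f"- Cmax (ng/mL, mean ± SD): {expo['cmax'].mean():.1f} ± {expo['cmax'].std(ddof=1):.1f}",
        f"- Tmax at 1 h: {round_half_away(100.0 * float(np.mean(tmax == 1.0)))}%, at 2 h: {round_half_away(100.0 * float(np.mean(tmax == 2.0)))}%",
        f"- C0 out of range: {int((expo['c0_flag'] != 'within').sum())}/{len(expo)}; AUC out of range: {int((expo['auc_flag'] != 'within').sum())}/{len(expo)}",
        "",
    ]
    return lines


def _section_pgx(outdir: str) -> list[str]:
    pgx = pd.read_csv(os.path.join(outdir, "pgx_report.csv")).set_index("quantity")["value"]
    lines = [
        "## CYP3A5",
        "",
        f"- genotyped: {int(pgx['n_genotyped'])} (*1/*1 {int(pgx['n_11'])}, *1/*3 {int(pgx['n_13'])}, *3/*3 {int(pgx['n_33'])})",
        f"- *3 allele frequency: {pgx['allele_freq_star3_pct']:.1f}%",
        f"- Hardy-Weinberg: chi2 = {pgx['hwe_chi2']:.2f} (df {int(pgx['hwe_df'])}), p = {pgx['hwe_p']:.2f}",
    ]
    if "tac_d_anova_f" in pgx.index:
        lines += [
            f"- TAC-D expressor vs non-expressor (mg/kg): {pgx['tac_d_mean_expressor']:.3f} vs {pgx['tac_d_mean_non_expressor']:.3f} "
            f"(ANOVA F = {pgx['tac_d_anova_f']:.2f}, p = {pgx['tac_d_anova_p']:.2g}; Mann-Whitney p = {pgx['tac_d_mwu_p']:.2g})",
            f"- AUC/TAC-D (ng·h/mL per mg/kg): {pgx['auc_per_dose_mean_expressor']:.0f} vs {pgx['auc_per_dose_mean_non_expressor']:.0f} "
            f"(ANOVA F = {pgx['auc_per_dose_anova_f']:.2f}, p = {pgx['auc_per_dose_anova_p']:.2g})",
        ]
    return lines + [""]


def _section_models(outdir: str) -> list[str]:
    models = pd.read_csv(os.path.join(outdir, "lss_models.csv"))
    lines = [
        "## Limited-sampling models (all subsets)",
        "",
        "| model | predictors | adj r2 | MAPE % | AICw | BICw | retained |",
        "|---|---|---|---|---|---|---|",
    ]
    for _, r in models.iterrows():
        lines.append(
            f"| {int(r['model'])} | {r['predictors']} | {r['adj_r2']:.4f} | {r['mape_pct']:.1f} "
            f"| {r['aic_weight']:.3f} | {r['bic_weight']:.3f} | {'yes' if r['retained'] else ''} |"
        )
    lines += ["", "Retained equations (adjusted r2 above threshold):", ""]
    for _, r in models[models["retained"]].iterrows():
        lines.append(f"- model {int(r['model'])}: {r['equation']}")
    return lines + [""]


def _section_validation(outdir: str) -> list[str]:
    path = os.path.join(outdir, "validation_report.csv")
    val = pd.read_csv(path)
    lines = [
        "## Validation against trapezoidal AUC(0-24)",
        "",
        "| equation | MAPE (median %) | APE mean ± SD % | frac APE > 15% | BA mean diff | BA limits |",
        "|---|---|---|---|---|---|",
    ]
    for _, r in val.iterrows():
        lines.append(
            f"| {r['equation']} | {r['mape_median_pct']:.1f} | {r['ape_mean_pct']:.1f} ± {r['ape_sd_pct']:.1f} "
            f"| {r['fraction_ape_above_threshold']:.3f} | {r['ba_mean_diff']:.1f} "
            f"| [{r['ba_loa_low']:.1f}, {r['ba_loa_high']:.1f}] |"
        )
    return lines + [""]


def render_report(outdir: str) -> str:
    """Assemble the run report from the stage outputs under ``outdir``.

    Missing stage outputs leave a flagged gap rather than failing, so a partial
    run still yields a readable document.
    """
    manifest_path = os.path.join(outdir, "manifest.json")
    lines = ["# Tacrolimus LSS pipeline report", ""]
    if os.path.exists(manifest_path):
        with open(manifest_path, encoding="utf-8") as fh:
            manifest = json.load(fh)
        lines.append(f"Seed: {manifest['config'].get('seed')}; package version {manifest['version']}.")
        lines.append("")
    for section in (_section_cohort, _section_pgx, _section_models, _section_validation):
        try:
            lines += section(outdir)
        except FileNotFoundError as exc:
            lines += [f"*Section unavailable: missing {os.path.basename(exc.filename)}*", ""]
    return "\n".join(lines)


def write_report(outdir: str, filename: str = "report.md") -> str:
    path = os.path.join(outdir, filename)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(render_report(outdir))
    return path
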