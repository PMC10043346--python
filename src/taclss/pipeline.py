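"""End-to-end runner: simulate (or load) -> exposure -> genetics -> LSS fit ->
validation, with a manifest that makes every run auditable and reproducible."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass

import pandas as pd

from . import __version__
from .cohort_sim import simulate_cohort, write_cohort
from .errors import TaclssError
from .io import PipelineConfig, read_cohort
from .lss_builder import fit_all_subsets, wide_concentrations
from .lss_validation import (
    REFERENCE_EQUATIONS,
    ExternalEquation,
    crossvalidate_lss,
    validate_equations,
)
from .pharmacogenetics import classify_expressor, pgx_report
from .pk_exposure import exposure_table

logger = logging.getLogger(__name__)

#: published equations validated alongside the best freshly fitted one
DEFAULT_VALIDATION_EQUATIONS = ("model12", "almeida_c0c1c4", "almeida_c0c2c4")


@dataclass
class RunManifest:
    config: dict
    version: str
    stages: dict  # stage -> {"rows": int} per written table
    checksums: dict  # filename -> sha256

    def to_json(self) -> str:
        return json.dumps(
            {
                "config": self.config,
                "version": self.version,
                "stages": self.stages,
                "checksums": self.checksums,
            },
            indent=2,
            sort_keys=True,
        )


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write(df: pd.DataFrame, outdir: str, name: str, manifest: RunManifest, stage: str) -> str:
    path = os.path.join(outdir, name)
    df.to_csv(path, index=False)
    manifest.stages.setdefault(stage, {})[name] = {"rows": len(df)}
    manifest.checksums[name] = _sha256(path)
    return path


def run_pipeline(
    config: PipelineConfig, outdir: str, cohort_dir: str | None = None
) -> RunManifest:
    """Run every stage, writing all tables plus ``manifest.json`` under outdir.

    When ``cohort_dir`` is given its tables are loaded instead of simulating.
    Deterministic given the config seed; a stage failure aborts with the stage
    name after persisting the partial manifest.
    """
    os.makedirs(outdir, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), version=__version__, stages={}, checksums={})
    stage = "simulate"
    try:
        if cohort_dir is None:
            tables = simulate_cohort(config.simulation)
            write_cohort(tables, outdir)
            tables = read_cohort(outdir)  # round-trip through the CSV contract
        else:
            tables = read_cohort(cohort_dir)
            write_cohort(tables, outdir)
        for name, df in (
            ("cohort_metadata.csv", tables.metadata),
            ("concentrations.csv", tables.concentrations),
        ):
            manifest.stages.setdefault(stage, {})[name] = {"rows": len(df)}
            manifest.checksums[name] = _sha256(os.path.join(outdir, name))

        stage = "exposure"
        exposure = exposure_table(
            tables.metadata, tables.concentrations, config.c0_range, config.auc_range
        )
        _write(exposure, outdir, "exposure_summary.csv", manifest, stage)

        stage = "pgx"
        pgx = pgx_report(tables.metadata, exposure)
        _write(pgx, outdir, "pgx_report.csv", manifest, stage)

        stage = "lss_fit"
        wide = wide_concentrations(tables.concentrations)
        auc = exposure.set_index("patient_id")["auc_0_24"]
        comparison, models_table = fit_all_subsets(
            wide, auc, config.candidates, config.retention_threshold
        )
        _write(models_table, outdir, "lss_models.csv", manifest, stage)

        stage = "lss_validate"
        equations: dict[str, ExternalEquation] = {}
        best = _best_retained(comparison)
        if best is not None:
            equations["fitted_best"] = best
        equations.update({n: REFERENCE_EQUATIONS[n] for n in DEFAULT_VALIDATION_EQUATIONS})
        groups = {
            "brand": tables.metadata.set_index("patient_id")["brand"].loc[auc.index].tolist(),
            "expressor": tables.metadata.set_index("patient_id")["genotype"]
            .loc[auc.index]
            .map(classify_expressor)
            .tolist(),
        }
        report, ba = validate_equations(equations, wide, auc, groups, config.ape_threshold)
        if best is not None:
            strata = groups["expressor"]
            cv = crossvalidate_lss(
                wide,
                auc,
                list(best.coefficients),
                folds=config.cv_folds,
                seed=config.seed,
                strata=strata,
                threshold=config.ape_threshold,
            )
            report.loc[report["equation"] == "fitted_best", "cv_mape_median_pct"] = cv.median
        _write(report, outdir, "validation_report.csv", manifest, stage)
        for name, agreement in ba.items():
            _write(agreement.pairs, outdir, f"bland_altman_{name}.csv", manifest, stage)

        stage = "manifest"
        with open(os.path.join(outdir, "manifest.json"), "w", encoding="utf-8") as fh:
            fh.write(manifest.to_json())
        return manifest
    except Exception as exc:
        with open(os.path.join(outdir, "manifest.partial.json"), "w", encoding="utf-8") as fh:
            fh.write(manifest.to_json())
        raise TaclssError(f"pipeline stage {stage!r} failed: {exc}") from exc


def _best_retained(comparison) -> ExternalEquation | None:
    """The retained model with the highest AIC weight, as a fixed equation."""
    candidates = [
        (w, m)
        for m, keep, w in zip(comparison.models, comparison.retained, comparison.aic_weights)
        if keep
    ]
    if not candidates:
        logger.warning("no model passed retention; validation covers published equations only")
        return None
    _, model = max(candidates, key=lambda t: t[0])
    return ExternalEquation("fitted_best", model.intercept, dict(model.coefficients))
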