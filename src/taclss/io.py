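"""Cohort file contracts: schema-validated reading and full-precision writing.

All tables are plain UTF-8 CSV with a header row and "." decimals. Numeric
values round-trip at full double precision; display rounding happens only in
the rendered report.
"""

from __future__ import annotations

import logging
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import pandas as pd
import yaml

from .cohort_sim import TIME_LABELS, CohortTables, SimulationConfig
from .errors import ValidationError
from .lss_builder import DEFAULT_ADJ_R2_THRESHOLD, DEFAULT_CANDIDATES
from .lss_validation import DEFAULT_APE_THRESHOLD
from .pk_exposure import DEFAULT_AUC_RANGE, DEFAULT_C0_RANGE

logger = logging.getLogger(__name__)

_METADATA_COLUMNS = ("patient_id", "weight_kg", "genotype", "daily_dose_mg", "tac_d_mg_per_kg", "brand")
_CONC_COLUMNS = ("patient_id", "label", "time_h", "conc_ng_ml")


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run (simulate -> ... -> report)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    candidates: tuple[str, ...] = DEFAULT_CANDIDATES
    retention_threshold: float = DEFAULT_ADJ_R2_THRESHOLD
    ape_threshold: float = DEFAULT_APE_THRESHOLD
    c0_range: tuple[float, float] = DEFAULT_C0_RANGE
    auc_range: tuple[float, float] = DEFAULT_AUC_RANGE
    cv_folds: int = 5
    seed: int = 0

    def __post_init__(self):
        if self.retention_threshold <= 0 or self.ape_threshold <= 0:
            raise ValidationError("thresholds must be positive")
        # one seed drives everything; the simulation inherits it
        self.simulation.seed = self.seed
        self.simulation.validate()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["simulation"] = asdict(self.simulation)
        return d

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        for key in ("candidates", "c0_range", "auc_range", "target_c0"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, **raw)


def _require_columns(df: pd.DataFrame, required: Sequence[str], name: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{name} is missing required columns {missing}")


def _require_numeric(df: pd.DataFrame, columns: Sequence[str], name: str) -> pd.DataFrame:
    df = df.copy()
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            rows = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 0-base
            raise ValidationError(f"{name}: non-numeric values in column {col!r} (file rows {rows})")
        if coerced.isna().any():
            rows = ", ".join(str(i + 2) for i in df.index[coerced.isna()][:5])
            raise ValidationError(f"{name}: empty values in column {col!r} (file rows {rows})")
        df[col] = coerced
    return df


def read_cohort(directory: str) -> CohortTables:
    """Load and cross-validate a cohort directory.

    Requires ``cohort_metadata.csv`` and ``concentrations.csv``;
    ``ground_truth.csv`` is attached when present. Every concentration row must
    reference a known patient; duplicate (patient, label) pairs are a hard
    error; patients lacking any of the six nominal time-points are excluded
    from downstream AUC work with a logged reason.
    """
    meta_path = os.path.join(directory, "cohort_metadata.csv")
    conc_path = os.path.join(directory, "concentrations.csv")
    for path in (meta_path, conc_path):
        if not os.path.exists(path):
            raise ValidationError(f"missing required cohort file {path}")
    # round_trip parser: stored doubles reload bit-for-bit
    metadata = pd.read_csv(meta_path, float_precision="round_trip")
    concentrations = pd.read_csv(conc_path, float_precision="round_trip")
    _require_columns(metadata, _METADATA_COLUMNS, "cohort_metadata.csv")
    _require_columns(concentrations, _CONC_COLUMNS, "concentrations.csv")
    metadata = _require_numeric(
        metadata, ("weight_kg", "daily_dose_mg", "tac_d_mg_per_kg"), "cohort_metadata.csv"
    )
    concentrations = _require_numeric(concentrations, ("time_h", "conc_ng_ml"), "concentrations.csv")

    dup_patients = metadata["patient_id"][metadata["patient_id"].duplicated()]
    if len(dup_patients):
        raise ValidationError(f"duplicate patient_id in metadata: {sorted(set(dup_patients))}")
    dups = concentrations.duplicated(subset=["patient_id", "label"])
    if dups.any():
        rows = ", ".join(str(i + 2) for i in concentrations.index[dups][:5])
        raise ValidationError(f"concentrations.csv: duplicate (patient_id, label) pairs at file rows {rows}")
    known = set(metadata["patient_id"])
    orphans = sorted(set(concentrations["patient_id"]) - known)
    if orphans:
        raise ValidationError(f"concentration rows reference unknown patients {orphans[:5]}")

    label_sets = concentrations.groupby("patient_id")["label"].agg(set)
    incomplete = [pid for pid, labels in label_sets.items() if not set(TIME_LABELS) <= labels]
    if incomplete:
        logger.warning(
            "excluding %d patient(s) with incomplete profiles from AUC analyses: %s",
            len(incomplete),
            incomplete,
        )
        concentrations = concentrations[~concentrations["patient_id"].isin(incomplete)]
        metadata = metadata[~metadata["patient_id"].isin(incomplete)]

    gt_path = os.path.join(directory, "ground_truth.csv")
    ground_truth = pd.read_csv(gt_path) if os.path.exists(gt_path) else pd.DataFrame()
    return CohortTables(
        metadata.reset_index(drop=True), concentrations.reset_index(drop=True), ground_truth
    )
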