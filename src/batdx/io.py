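"""Delimited-text readers/writers and pipeline configuration.

Two tables carry the data:

``subjects.csv`` — one row per individual:
    subject_id, cohort, severity, peanut_group, profilin_sensitized, age,
    sex, total_ige, sige_prup3, sige_arah9, spt_peach_area, spt_peanut_area

``bat_long.csv`` — one row per stimulation well (long/tidy format):
    subject_id, allergen, marker, concentration_ug_ml, activation_pct,
    background_pct

Concentrations are stored as µg/mL decimals; the unstimulated background is
a per-series column, never a 0-concentration row. Unknown columns are
preserved on read and passed through on write. Writing then re-reading
reproduces all values bit-exactly (floats are serialized with shortest
round-trip repr).
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, SchemaError, ValidationError
from .types import BATSeries, SimulationConfig, SubjectRecord

__all__ = [
    "SUBJECT_COLUMNS", "BAT_COLUMNS", "PipelineConfig",
    "read_subjects", "write_subjects", "read_bat_long", "write_bat_long",
    "load_pipeline_config",
]

SUBJECT_COLUMNS = [f.name for f in dataclasses.fields(SubjectRecord)]
BAT_COLUMNS = ["subject_id", "allergen", "marker", "concentration_ug_ml",
               "activation_pct", "background_pct"]


def _require_columns(df: pd.DataFrame, required, path):
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")


def write_subjects(subjects, path):
    rows = [dataclasses.asdict(s) for s in subjects]
    df = pd.DataFrame(rows, columns=SUBJECT_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_subjects(path):
    """Parse subjects.csv into SubjectRecords (extra columns ignored but
    preserved in the returned frame)."""
    # keep_default_na: the literal peanut-group label "NA" must survive
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    _require_columns(df, SUBJECT_COLUMNS, path)
    subjects = []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        for col in ("total_ige", "sige_prup3", "sige_arah9",
                    "spt_peach_area", "spt_peanut_area", "age"):
            if row[col] < 0:
                raise ValidationError(f"{path}:{line}: {col} = {row[col]} is negative")
        subjects.append(SubjectRecord(
            subject_id=str(row.subject_id), cohort=str(row.cohort),
            severity=str(row.severity), peanut_group=str(row.peanut_group),
            profilin_sensitized=bool(row.profilin_sensitized),
            age=float(row.age), sex=str(row.sex),
            total_ige=float(row.total_ige), sige_prup3=float(row.sige_prup3),
            sige_arah9=float(row.sige_arah9),
            spt_peach_area=float(row.spt_peach_area),
            spt_peanut_area=float(row.spt_peanut_area)))
    return subjects, df


def write_bat_long(series, concentrations, path):
    conc = np.asarray(concentrations, dtype=float)
    rows = []
    for s in series:
        for c, a in zip(conc, s.activation_pct):
            rows.append({
                "subject_id": s.subject_id, "allergen": s.allergen,
                "marker": s.marker, "concentration_ug_ml": c,
                "activation_pct": a, "background_pct": s.background_pct})
    df = pd.DataFrame(rows, columns=BAT_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_bat_long(path):
    """Parse bat_long.csv back into ``(series, concentrations, frame)``.

    Row order within a (subject, allergen, marker) block is re-sorted by
    concentration; every block must share one concentration grid.
    """
    df = pd.read_csv(path)
    _require_columns(df, BAT_COLUMNS, path)
    for i, row in df.iterrows():
        line = i + 2
        for col in ("activation_pct", "background_pct"):
            v = row[col]
            if not (0.0 <= v <= 100.0):
                raise ValidationError(
                    f"{path}:{line}: {col} = {v} outside [0, 100]")
        if row.concentration_ug_ml <= 0:
            raise ValidationError(
                f"{path}:{line}: concentration_ug_ml must be > 0")
    if df.empty:
        return [], np.asarray([]), df
    concentrations = np.sort(df["concentration_ug_ml"].unique())
    series = []
    for (sid, allergen, marker), block in df.groupby(
            ["subject_id", "allergen", "marker"], sort=True):
        block = block.sort_values("concentration_ug_ml")
        if not np.array_equal(block["concentration_ug_ml"].to_numpy(),
                              concentrations):
            raise ValidationError(
                f"{path}: series {sid}/{allergen}/{marker} does not cover "
                "the common concentration grid")
        series.append(BATSeries(
            subject_id=str(sid), allergen=str(allergen), marker=str(marker),
            background_pct=float(block["background_pct"].iloc[0]),
            activation_pct=block["activation_pct"].to_numpy(dtype=float)))
    return series, concentrations, df


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings (YAML-loadable, one top-level seed)."""

    out_dir: str = "batdx_out"
    seed: int = 0
    simulate: bool = True
    subjects_path: str = None       # used when simulate is False
    bat_long_path: str = None
    n_selected: int = 3             # discriminating concentrations to keep
    markers: tuple = ("CD63", "CD203c")
    cutoff_source: str = "derived"  # "derived" | "paper"
    cutoff_criterion: str = "youden"
    min_peak: float = 5.0
    fold_over_background: float = 2.0
    evaluate_all_concentrations: bool = False  # positivity over all 7 instead of the selected 3
    simulation: dict = field(default_factory=dict)  # SimulationConfig overrides

    def validate(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")
        if self.cutoff_source not in ("derived", "paper"):
            raise ConfigurationError(
                f"cutoff_source must be 'derived' or 'paper', got {self.cutoff_source!r}")
        if not self.simulate:
            for p in (self.subjects_path, self.bat_long_path):
                if not p or not Path(p).exists():
                    raise ConfigurationError(
                        f"input table {p!r} does not exist (simulate=false)")
        return self

    def simulation_config(self) -> SimulationConfig:
        cfg = SimulationConfig(seed=self.seed, **self.simulation)
        cfg.validate()
        return cfg


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {', '.join(sorted(unknown))}")
    return PipelineConfig(**raw).validate()
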