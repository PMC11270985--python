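"""Typed readers and writers for trial tables, reference-toxicity tables and
prediction reports, plus run configuration and logging.

The canonical in-memory containers are pandas DataFrames with documented,
validated column sets.  A *trial table* holds one row per exposure group:
clothianidin concentration (µg/L), prochloraz concentration (µg/L),
temperature (°C), population label, number of animals exposed and number
immobile after the test duration.  Replicate rows for the same treatment are
allowed and are summed by downstream fitting.
"""

from __future__ import annotations

import dataclasses
import logging
import sys
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import SchemaError, ValidationError

logger = logging.getLogger("multistress")

#: required columns of a trial table, in canonical order
TRIAL_COLUMNS = (
    "clothianidin_conc",
    "prochloraz_conc",
    "temperature",
    "population",
    "n_exposed",
    "n_immobile",
)

#: optional trial-table columns carried through when present
TRIAL_OPTIONAL = ("stream", "replicate", "duration_h")

#: required columns of a reference-toxicity table
REFERENCE_COLUMNS = ("compound", "measured_conc", "reference_ec50")
REFERENCE_OPTIONAL = ("sample_id", "site_id", "year")

REPORT_COLUMNS = (
    "design",
    "population",
    "temperature",
    "prochloraz",
    "model",
    "observed_ec50",
    "predicted_ec50",
    "mdr",
    "classification",
)


def configure_logging(verbosity: int = 0) -> None:
    """Route package logging to stderr; ``verbosity`` 0=WARNING, 1=INFO, 2=DEBUG."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level)


@dataclasses.dataclass
class RunConfig:
    """Run-level knobs shared across the pipeline.

    Parameters
    ----------
    capacity_alpha, capacity_beta
        Shape parameters of the beta stress-capacity distribution on [0, 1].
    effect_level
        The x of ECx, in percent (0 < x < 100); 50 gives the EC50.
    report_decimals
        Decimal places used when formatting reports (round-half-even).
    relative_ecx
        If True (default), ECx is rescaled between the fitted asymptotes;
        if False it is taken on the absolute effect scale.
    stress_window
        Number of tested doses on each side of the fitted EC50 used when
        quantifying an added stressor's General-Stress.
    seed
        Seed for any simulation launched from this configuration.
    """

    capacity_alpha: float = 3.2
    capacity_beta: float = 3.2
    effect_level: float = 50.0
    report_decimals: int = 2
    relative_ecx: bool = True
    stress_window: int = 2
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.effect_level < 100.0:
            raise ValidationError(
                f"effect_level must be in (0, 100), got {self.effect_level}"
            )
        if self.capacity_alpha <= 0 or self.capacity_beta <= 0:
            raise ValidationError("stress-capacity shape parameters must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise SchemaError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


def _resolve_columns(frame: pd.DataFrame, required: Sequence[str],
                     optional: Sequence[str] = ()) -> pd.DataFrame:
    """Map case-insensitive headers onto canonical names; fail on misses."""
    lookup = {str(c).strip().lower(): c for c in frame.columns}
    rename = {}
    for name in (*required, *optional):
        if name in lookup:
            rename[lookup[name]] = name
    missing = [name for name in required if name not in rename.values()
               and name not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {missing}")
    return frame.rename(columns=rename)


def validate_trial_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate trial-record invariants, reporting the offending row index."""
    table = _resolve_columns(table, TRIAL_COLUMNS, TRIAL_OPTIONAL)
    numeric = ["clothianidin_conc", "prochloraz_conc", "temperature",
               "n_exposed", "n_immobile"]
    for col in numeric:
        table[col] = pd.to_numeric(table[col], errors="coerce")
    for i, row in enumerate(table.itertuples(index=False)):
        if not np.isfinite(row.clothianidin_conc) or row.clothianidin_conc < 0:
            raise ValidationError(
                f"row {i}: clothianidin_conc must be finite and >= 0", row=i)
        if not np.isfinite(row.prochloraz_conc) or row.prochloraz_conc < 0:
            raise ValidationError(
                f"row {i}: prochloraz_conc must be finite and >= 0", row=i)
        if not np.isfinite(row.temperature):
            raise ValidationError(f"row {i}: temperature must be finite", row=i)
        if row.n_exposed <= 0:
            raise ValidationError(f"row {i}: n_exposed must be > 0", row=i)
        if not 0 <= row.n_immobile <= row.n_exposed:
            raise ValidationError(
                f"row {i}: n_immobile={row.n_immobile} outside "
                f"[0, n_exposed={row.n_exposed}]", row=i)
    return table


def read_trial_table(path, sep=None) -> pd.DataFrame:
    """Read a delimited trial table (comma default, tab accepted).

    Returns a validated DataFrame with canonical column names and original
    row order.  Replicate rows for the same treatment are preserved.
    """
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    return validate_trial_table(frame)


def write_trial_table(table: pd.DataFrame, path, sep=",") -> None:
    validate_trial_table(table).to_csv(path, sep=sep, index=False)


def read_reference_table(path, sep=None) -> pd.DataFrame:
    """Read a reference-toxicity table (compound, measured_conc, reference_ec50).

    Optional ``sample_id``/``site_id``/``year`` columns support per-sample and
    per-site toxic-unit aggregation.
    """
    frame = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    frame = _resolve_columns(frame, REFERENCE_COLUMNS, REFERENCE_OPTIONAL)
    frame["measured_conc"] = pd.to_numeric(frame["measured_conc"])
    frame["reference_ec50"] = pd.to_numeric(frame["reference_ec50"])
    for i, row in enumerate(frame.itertuples(index=False)):
        if not row.reference_ec50 > 0:
            raise ValidationError(f"row {i}: reference_ec50 must be > 0", row=i)
        if row.measured_conc < 0:
            raise ValidationError(f"row {i}: measured_conc must be >= 0", row=i)
    return frame


def report_round(value: float, decimals: int = 2) -> float:
    """Round-half-even at the report layer; raw values stay unrounded upstream."""
    if value is None or not np.isfinite(value):
        return float("nan")
    return float(np.round(value, decimals))


def write_report(records: Iterable, path, config: RunConfig | None = None) -> pd.DataFrame:
    """Write prediction records to a delimited report.

    One row per (condition, model) with observed EC50, predicted EC50, MDR
    and the synergy classification, formatted at the configured precision.
    Raises :class:`ValidationError` on an empty record list and creates no file.
    """
    config = config or RunConfig()
    records = list(records)
    if not records:
        raise ValidationError("cannot write a report from an empty record list")
    rows = []
    for rec in records:
        pop, temp, proch = rec.condition
        rows.append({
            "design": rec.design,
            "population": pop,
            "temperature": temp,
            "prochloraz": proch,
            "model": rec.model,
            "observed_ec50": report_round(rec.observed_ec50, config.report_decimals),
            "predicted_ec50": report_round(rec.predicted_ec50, config.report_decimals),
            "mdr": report_round(rec.mdr, config.report_decimals),
            "classification": rec.classification,
        })
    frame = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    frame.to_csv(path, index=False,
                 float_format=f"%.{config.report_decimals}f")
    return frame


def read_report(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    return _resolve_columns(frame, REPORT_COLUMNS)
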