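"""Toxic units (TU) for measured environmental concentrations.

The toxic unit of a compound in a water sample is the log10 ratio of its
measured concentration to the acute LC50/EC50 of the most sensitive standard
test species, ``TU = log10(C / EC50_ref)``.  A sample's toxic pressure is
summarised by the compound with the maximum TU (TU_max); site-level pressure
aggregates TU_max across sampling campaigns and years.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import DomainError, ValidationError


@dataclasses.dataclass(frozen=True)
class ToxicUnitResult:
    """One compound-in-sample toxic unit on the log10 scale.

    ``below_detection`` marks a zero measured concentration, for which the
    log ratio is undefined; flagged results are excluded from maxima.
    """

    compound: str
    tu_log10: float
    sample_id: str = ""
    site_id: str = ""
    below_detection: bool = False

    @property
    def tu_linear(self) -> float:
        return float(10.0 ** self.tu_log10) if not self.below_detection else 0.0


def toxic_unit(compound: str, measured_conc: float, reference_ec50: float,
               sample_id: str = "", site_id: str = "") -> ToxicUnitResult:
    """TU = log10(measured / reference EC50); zero concentration is flagged
    below-detection rather than mapped to -infinity."""
    if not reference_ec50 > 0:
        raise ValidationError("reference_ec50 must be > 0")
    if measured_conc < 0:
        raise ValidationError("measured_conc must be >= 0")
    if measured_conc == 0:
        return ToxicUnitResult(compound, float("nan"), sample_id, site_id,
                               below_detection=True)
    return ToxicUnitResult(
        compound, float(np.log10(measured_conc / reference_ec50)),
        sample_id, site_id)


def min_reference(candidates: Sequence[float]) -> float:
    """Reference EC50 over candidate standard species: the most sensitive
    (minimum) of the provided values."""
    vals = [float(v) for v in candidates]
    if not vals or any(v <= 0 for v in vals):
        raise ValidationError("candidate reference EC50s must be positive")
    return min(vals)


def tu_max(results: Iterable[ToxicUnitResult]) -> ToxicUnitResult:
    """The unflagged result with the highest log TU; compound-name order
    breaks ties deterministically."""
    usable = [r for r in results if not r.below_detection]
    if not usable:
        raise DomainError("tu_max over a sample with no detected compound")
    return max(usable, key=lambda r: (r.tu_log10, r.compound))


def toxic_units_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Vectorised toxic units for a reference-toxicity table.

    Adds ``tu_log10`` and ``below_detection`` columns; requires ``compound``,
    ``measured_conc``, ``reference_ec50``.
    """
    if (frame["reference_ec50"] <= 0).any():
        raise ValidationError("reference_ec50 must be > 0 in every row")
    out = frame.copy()
    conc = out["measured_conc"].to_numpy(dtype=float)
    ref = out["reference_ec50"].to_numpy(dtype=float)
    with np.errstate(divide="ignore"):
        tu = np.where(conc > 0, np.log10(np.where(conc > 0, conc, 1.0) / ref),
                      np.nan)
    out["tu_log10"] = tu
    out["below_detection"] = conc == 0
    return out


def sample_tu_max(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-sample TU_max over compounds (``sample_id`` grouping)."""
    tus = toxic_units_frame(frame)
    detected = tus.loc[~tus["below_detection"]].sort_values(
        ["tu_log10", "compound"])
    if detected.empty:
        raise DomainError("no detected compound in any sample")
    keys = [k for k in ("site_id", "year", "sample_id") if k in tus.columns]
    if "sample_id" not in keys:
        raise ValidationError("sample_tu_max needs a sample_id column")
    # last row per group after the (tu, compound) sort = max with the
    # documented compound-name tie-break
    winners = detected.groupby(keys, sort=True).tail(1)
    return (winners[keys + ["compound", "tu_log10"]]
            .sort_values(keys).reset_index(drop=True))


def aggregate_site_tu(frame: pd.DataFrame) -> dict:
    """Site-level toxic pressure from multi-year sampling.

    Rule (documented choice; the aggregation statistic is not standardised):
    within each campaign (``year``) take the maximum of the per-sample
    TU_max values, then average the campaign maxima across years.  Returns
    the per-sample, per-campaign and per-site layers for audit.
    """
    per_sample = sample_tu_max(frame)
    if "year" not in per_sample.columns:
        per_sample = per_sample.assign(year=0)
    if "site_id" not in per_sample.columns:
        per_sample = per_sample.assign(site_id="site")
    per_campaign = (per_sample.groupby(["site_id", "year"])["tu_log10"]
                    .max().rename("campaign_tu_max").reset_index())
    per_site = (per_campaign.groupby("site_id")["campaign_tu_max"]
                .mean().rename("site_tu").reset_index())
    return {
        "per_sample": per_sample,
        "per_campaign": per_campaign,
        "per_site": per_site,
        "rule": "max TU_max per campaign, mean of campaign maxima across years",
    }
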