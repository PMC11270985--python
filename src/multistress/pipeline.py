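"""Study orchestration: comparison designs, Table-style prediction reports,
synergism-vs-total-stress regression and group comparisons.

Two comparison layouts are supported.  Under *mixture toxicity* each
(population, temperature, prochloraz > 0) condition is compared with the
prochloraz-free control at the same temperature, isolating the
clothianidin-prochloraz interaction.  Under *multiple stress* every
condition at elevated temperature (19/22 °C, any prochloraz) is compared
with the best-case control of the same population at 16 °C without
prochloraz, so warming and the fungicide jointly enter the comparison.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import io as mio
from .doseresponse import LogLogistic5
from .exceptions import ConfigurationError, DomainError, ValidationError
from .nullmodels import (PredictionRecord, classify_mdr, mdr,
                         predict_ec50_with_costressor)
from .sam import (StressCapacityDistribution, quantify_stressor_stress,
                  sam_predict_ec50)

CONDITION_KEYS = ["population", "temperature", "prochloraz_conc"]


@dataclasses.dataclass(frozen=True)
class ComparisonDesign:
    """A comparison layout: which control anchors each tested condition."""

    mode: str  # "mixture_toxicity" | "multiple_stress"

    def control_for(self, condition: tuple, base_temperature: float) -> tuple:
        pop, temp, proch = condition
        if self.mode == "mixture_toxicity":
            return (pop, temp, 0.0)
        if self.mode == "multiple_stress":
            return (pop, base_temperature, 0.0)
        raise ConfigurationError(f"unknown design mode {self.mode!r}")

    def is_tested(self, condition: tuple, base_temperature: float) -> bool:
        """Conditions entering the report as non-control rows."""
        pop, temp, proch = condition
        if self.mode == "mixture_toxicity":
            return proch > 0
        if self.mode == "multiple_stress":
            return temp > base_temperature
        raise ConfigurationError(f"unknown design mode {self.mode!r}")


def mixture_design() -> ComparisonDesign:
    return ComparisonDesign("mixture_toxicity")


def multiple_stress_design() -> ComparisonDesign:
    return ComparisonDesign("multiple_stress")


@dataclasses.dataclass(frozen=True)
class SynergyPoint:
    """One condition's EA-based synergism against its total General-Stress."""

    condition: tuple
    design: str
    total_stress: float
    mdr_ea: float


@dataclasses.dataclass(frozen=True)
class RegressionSummary:
    slope: float
    intercept: float
    r2_adj: float
    fvalue: float
    df_resid: int
    pvalue: float


class MultiStressStudy:
    """A fitted-curve cache plus design runner over one trial table.

    Observed curves are fitted on pooled counts per condition, i.e. on
    group-averaged survival across replicate vessels and streams of the
    same population class.
    """

    def __init__(self, table: pd.DataFrame, config: mio.RunConfig | None = None):
        self.table = mio.validate_trial_table(table)
        self.config = config or mio.RunConfig()
        self.capacity = StressCapacityDistribution(
            self.config.capacity_alpha, self.config.capacity_beta)
        self.base_temperature = float(self.table["temperature"].min())
        self._fits: dict = {}

    # -- condition handling -------------------------------------------------

    def conditions(self) -> list:
        combos = (self.table[CONDITION_KEYS].drop_duplicates()
                  .sort_values(CONDITION_KEYS))
        return [tuple(r) for r in combos.itertuples(index=False)]

    def subset(self, condition: tuple) -> pd.DataFrame:
        pop, temp, proch = condition
        mask = ((self.table["population"] == pop)
                & (self.table["temperature"] == temp)
                & (self.table["prochloraz_conc"] == proch))
        return self.table.loc[mask]

    def curve(self, condition: tuple):
        """Fitted LL5 curve for one condition (cached)."""
        if condition not in self._fits:
            sub = self.subset(condition)
            if sub.empty:
                raise ConfigurationError(f"no data for condition {condition}")
            self._fits[condition] = LogLogistic5.from_table(sub).fit()
        return self._fits[condition]

    def costressor_effect(self, condition: tuple, control: tuple) -> float:
        """Marginal effect of the co-stressor(s) at its fixed level: the
        condition curve's fitted lower asymptote (the clothianidin-free
        response floor, estimated jointly from the control and low-dose
        treatments), Abbott-corrected against the control curve's background
        immobility.  The fitted floor is used instead of the raw dose-0
        fraction because a single treatment of a dozen animals estimates it
        with sizable binomial noise."""
        sub = self.subset(condition)
        if (sub["clothianidin_conc"] == 0).sum() == 0:
            return 0.0
        p0 = float(self.curve(condition).params["lower_c"])
        c = float(self.curve(control).params["lower_c"])
        return max(0.0, (p0 - c) / (1.0 - c))

    # -- the main computation ----------------------------------------------

    def fit(self, design: ComparisonDesign,
            models: Sequence[str] = ("CA", "EA", "SAM")) -> "StudyResults":
        records = run_design(self, design, models)
        return StudyResults(self, design, records)


def run_design(study: MultiStressStudy | pd.DataFrame, design: ComparisonDesign,
               models: Sequence[str] = ("CA", "EA", "SAM"),
               config: mio.RunConfig | None = None) -> list:
    """Run one comparison design: per tested condition and null model,
    observed EC50, predicted EC50, MDR and classification.

    Output is ordered by (population, temperature, prochloraz, model).
    """
    if not isinstance(study, MultiStressStudy):
        study = MultiStressStudy(study, config)
    base = study.base_temperature
    records = []
    for condition in study.conditions():
        if not design.is_tested(condition, base):
            continue
        control = design.control_for(condition, base)
        if study.subset(control).empty:
            raise ConfigurationError(
                f"condition {condition} has no control {control} in the table")
        observed = study.curve(condition).ec(
            study.config.effect_level, ci="none",
            relative=study.config.relative_ecx).dose
        ctrl_curve = study.curve(control)
        e_cos = study.costressor_effect(condition, control)
        # CA sums concentrations, so only the chemical co-stressor can
        # contribute a dose equivalent: its marginal effect is taken
        # against the same-temperature prochloraz-free condition, leaving
        # temperature out of the isobole (it has no concentration)
        chem_control = (condition[0], condition[1], 0.0)
        if study.subset(chem_control).empty:
            e_cos_chem = 0.0
        else:
            e_cos_chem = study.costressor_effect(condition, chem_control)
        for model in models:
            model = model.upper()
            if model in ("CA", "EA"):
                predicted = predict_ec50_with_costressor(
                    model, ctrl_curve, e_cos if model == "EA" else e_cos_chem)
            elif model == "SAM":
                s_extra = quantify_stressor_stress(
                    ctrl_curve, study.subset(condition), study.capacity,
                    window=study.config.stress_window)
                predicted = sam_predict_ec50(ctrl_curve, s_extra.value,
                                             study.capacity)
            else:
                raise ValueError(f"unknown model {model!r}")
            ratio = mdr(predicted, observed)
            records.append(PredictionRecord(
                condition=condition, design=design.mode, model=model,
                observed_ec50=float(observed), predicted_ec50=float(predicted),
                mdr=ratio, classification=classify_mdr(ratio)))
    return records


class StudyResults:
    """Prediction records of one design run with report/summary accessors."""

    def __init__(self, study, design, records):
        self.study = study
        self.design = design
        self.records = records

    @property
    def frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            pop, temp, proch = r.condition
            rows.append({"population": pop, "temperature": temp,
                         "prochloraz": proch, "model": r.model,
                         "observed_ec50": r.observed_ec50,
                         "predicted_ec50": r.predicted_ec50,
                         "mdr": r.mdr, "classification": r.classification})
        return pd.DataFrame(rows)

    def write_report(self, path) -> pd.DataFrame:
        return mio.write_report(self.records, path, self.study.config)

    def summary(self) -> str:
        frame = self.frame.copy()
        dec = self.study.config.report_decimals
        for col in ("observed_ec50", "predicted_ec50", "mdr"):
            frame[col] = frame[col].map(lambda v: mio.report_round(v, dec))
        header = f"Combined-effect predictions ({self.design.mode})"
        return header + "\n" + frame.to_string(index=False)


# -- synergism vs total stress (EA null model) -------------------------------

def linear_regression(x: Sequence[float], y: Sequence[float]) -> RegressionSummary:
    """OLS of y on x with intercept; the generic site-level utility."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValidationError("need at least 3 points for a regression")
    if np.ptp(x) == 0:
        raise DomainError("degenerate predictor: no variance in x")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionSummary(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r2_adj=float(res.rsquared_adj), fvalue=float(res.fvalue),
        df_resid=int(res.df_resid), pvalue=float(res.f_pvalue))


def synergism_regression(points: Iterable[SynergyPoint]) -> RegressionSummary:
    """OLS of EA-based MDR on total General-Stress (the synergism-vs-stress
    association); residual df = n - 2."""
    points = list(points)
    return linear_regression([p.total_stress for p in points],
                             [p.mdr_ea for p in points])


def synergy_points(study: MultiStressStudy,
                   reference_population: str = "reference") -> list:
    """EA-MDR vs total General-Stress points pooled over both designs.

    Component stresses are quantified from the reference population's
    curves (prochloraz from the same-temperature shift, warming from the
    16 °C shift); the fitness cost of adaptation is quantified, per
    condition, as the excess General-Stress of the agricultural response
    over the reference response under the same co-stressors (floored at 0).
    """
    cap = study.capacity
    window = study.config.stress_window
    base = study.base_temperature

    def quantified(alone_cond, combined_cond) -> float:
        return quantify_stressor_stress(
            study.curve(alone_cond), study.subset(combined_cond), cap,
            window=window).value

    points = []
    for design in (mixture_design(), multiple_stress_design()):
        records = {r.condition: r for r in run_design(study, design, ("EA",))}
        for condition, rec in records.items():
            pop, temp, proch = condition
            total = 0.0
            if proch > 0:
                total += quantified((reference_population, temp, 0.0),
                                    (reference_population, temp, proch))
            if design.mode == "multiple_stress" and temp > base:
                total += quantified((reference_population, base, 0.0),
                                    (reference_population, temp, 0.0))
            if pop != reference_population:
                ctrl = design.control_for(condition, base)
                ref_condition = (reference_population, temp, proch)
                ref_ctrl = design.control_for(ref_condition, base)
                s_pop = quantified(ctrl, condition)
                s_ref = quantified(ref_ctrl, ref_condition)
                total += max(0.0, s_pop - s_ref)
            points.append(SynergyPoint(condition=condition, design=design.mode,
                                       total_stress=total, mdr_ea=rec.mdr))
    return points


# -- group comparisons -------------------------------------------------------

def fold_tolerance(ec50_a: float, ec50_b: float) -> float:
    """Fold difference a/b, report-rounded to one decimal."""
    if not (ec50_a > 0 and ec50_b > 0):
        raise DomainError("fold_tolerance needs positive EC50s")
    return mio.report_round(ec50_a / ec50_b, 1)


def compare_groups(values_a: Sequence[float], values_b: Sequence[float],
                   paired: bool = False, log_transform: bool = False,
                   variance_alpha: float = 0.05) -> tuple:
    """t-type comparison of two groups: paired t when ``paired``; otherwise
    pooled two-sample t if a two-sided F-ratio pre-check accepts equal
    variances at ``variance_alpha``, else Welch's t.

    Returns (statistic, degrees of freedom, p-value).  ``log_transform``
    applies ln(x) first (the usual transform for EC50s).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least two values per group")
    if log_transform:
        if np.any(a <= 0) or np.any(b <= 0):
            raise DomainError("ln transform needs positive values")
        a, b = np.log(a), np.log(b)
    if paired:
        if a.size != b.size:
            raise ValidationError("paired comparison needs equal-length groups")
        res = stats.ttest_rel(a, b)
        return float(res.statistic), float(a.size - 1), float(res.pvalue)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va <= 0 and vb <= 0:
        # identical-variance degenerate case: pooled t (0/0-safe via scipy)
        equal_var = True
    else:
        big, small = max(va, vb), max(min(va, vb), 1e-300)
        dfx = (a.size - 1, b.size - 1) if va >= vb else (b.size - 1, a.size - 1)
        p_f = 2.0 * min(stats.f.sf(big / small, *dfx),
                        1.0 - stats.f.sf(big / small, *dfx))
        equal_var = p_f >= variance_alpha
    res = stats.ttest_ind(a, b, equal_var=equal_var)
    if equal_var:
        df = float(a.size + b.size - 2)
    else:
        df = float((va / a.size + vb / b.size) ** 2
                   / ((va / a.size) ** 2 / (a.size - 1)
                      + (vb / b.size) ** 2 / (b.size - 1)))
    return float(res.statistic), df, float(res.pvalue)
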