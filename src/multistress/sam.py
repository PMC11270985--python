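"""The stress addition model (SAM).

SAM assumes every individual carries a "General-Stress capacity" drawn from
a common distribution on [0, 1].  A stressor of General-Stress level
:math:`S` kills the individuals whose capacity is below :math:`S`, so the
surviving fraction is :math:`N(S) = 1 - F(S)` with :math:`F` the capacity
distribution's CDF: :math:`N(0) = 1` (no stress, full survival) and
:math:`N(S \\ge 1) = 0` (stress beyond any capacity).  Independently acting
stressors add on the General-Stress scale, :math:`S = \\sum_i S_i`, and the
sum is transformed back to survival.

The capacity distribution here is a beta law; the default shape (3.2, 3.2)
follows the established SAM reference implementation, since the framework
itself fixes only the boundary behaviour.  Both shapes are configurable.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .exceptions import DomainError, ValidationError

logger = logging.getLogger("multistress")


class StressCapacityDistribution:
    """Beta stress-capacity law on [0, 1] mapping General-Stress <-> survival."""

    def __init__(self, alpha: float = 3.2, beta: float = 3.2):
        if alpha <= 0 or beta <= 0:
            raise ValidationError("beta shape parameters must be > 0")
        self.alpha = float(alpha)
        self.beta = float(beta)
        self._dist = stats.beta(self.alpha, self.beta)

    def __repr__(self):
        return f"StressCapacityDistribution(alpha={self.alpha}, beta={self.beta})"

    def survival(self, stress):
        """N(S) = 1 - F(S): survival under General-Stress S >= 0."""
        stress = np.asarray(stress, dtype=float)
        if np.any(stress < 0):
            raise DomainError("General-Stress must be >= 0")
        return 1.0 - self._dist.cdf(np.clip(stress, 0.0, 1.0))

    def stress(self, survival):
        """S = F^{-1}(1 - survival): the General-Stress giving this survival."""
        survival = np.asarray(survival, dtype=float)
        if np.any((survival < 0) | (survival > 1)):
            raise DomainError("survival must lie in [0, 1]")
        return self._dist.ppf(1.0 - survival)


@dataclasses.dataclass(frozen=True)
class StressLevel:
    """A non-negative General-Stress contribution with its source label."""

    value: float
    source: str = ""

    def __post_init__(self):
        if not np.isfinite(self.value) or self.value < 0:
            raise ValidationError("General-Stress must be finite and >= 0")


@dataclasses.dataclass
class GeneralStressEstimate:
    """An added stressor's General-Stress plus the per-dose audit trail."""

    value: float
    per_dose: pd.DataFrame
    window: tuple


def _as_value(s) -> float:
    return float(s.value) if isinstance(s, StressLevel) else float(s)


def stress_to_survival(s, dist: StressCapacityDistribution) -> float:
    """Survival under General-Stress ``s`` (scalar or StressLevel)."""
    return float(dist.survival(_as_value(s)))


def survival_to_stress(survival: float, dist: StressCapacityDistribution) -> float:
    """General-Stress producing ``survival``; exact inverse of
    :func:`stress_to_survival` on [0, 1]."""
    return float(dist.stress(survival))


def total_general_stress(stresses: Iterable) -> float:
    """Sum of independently acting stressors' General-Stress levels."""
    return float(sum(_as_value(s) for s in stresses))


def _survival_lookup(combined, dist) -> Mapping[float, float]:
    """Normalise 'combined' input to a dose -> survival mapping.

    Accepts a trial table (immobile/exposed counts; replicate rows pooled)
    or a plain mapping of dose to survival fraction.
    """
    if isinstance(combined, Mapping):
        return {float(k): float(v) for k, v in combined.items()}
    table = combined
    grouped = (pd.DataFrame({
        "dose": table["clothianidin_conc"].to_numpy(dtype=float),
        "k": table["n_immobile"].to_numpy(dtype=float),
        "n": table["n_exposed"].to_numpy(dtype=float),
    }).groupby("dose").sum())
    # Anscombe-style continuity correction keeps all-dead / all-alive
    # treatments on the open interval so their stress stays finite
    return {float(d): float(1.0 - (row.k + 0.5) / (row.n + 1.0))
            for d, row in grouped.iterrows()}


def quantify_stressor_stress(tox_curve_alone, combined, dist,
                             window: int = 2) -> GeneralStressEstimate:
    """General-Stress exerted by an added stressor, from the survival shift
    it causes around the EC50 of the primary toxicant alone.

    For each tested dose within the window (the ``window`` nearest tested
    doses on each side of the fitted EC50, plus any dose equal to it), the
    alone survival (from the fitted curve) and the combined survival
    (observed) are both converted to General-Stress; the per-dose differences
    are averaged and floored at zero.  Negative per-dose contributions
    (combined survival above alone survival) are kept in the audit frame but
    the aggregate is floored, with a log warning.
    """
    ec50 = tox_curve_alone.ec(50.0, ci="none").dose
    if not np.isfinite(ec50) or ec50 <= 0:
        raise DomainError("EC50 of the alone curve must be finite and > 0")
    survival = _survival_lookup(combined, dist)
    doses = np.array(sorted(d for d in survival if d > 0))
    if doses.size == 0:
        raise DomainError("combined data contain no positive dose")
    rows = []
    for dose in doses:
        surv_alone = float(1.0 - tox_curve_alone.effect_at(float(dose)))
        surv_comb = survival[float(dose)]
        s_alone = survival_to_stress(surv_alone, dist)
        s_comb = survival_to_stress(surv_comb, dist)
        # a dose where either response is saturated (survival at 0 or 1,
        # i.e. stress censored at the capacity bounds) carries no
        # information about the added stress and never enters the window
        censored = not (0.0 < surv_comb < 1.0 and 0.0 < surv_alone < 1.0)
        rows.append({"dose": float(dose), "survival_alone": surv_alone,
                     "survival_combined": surv_comb,
                     "stress_alone": s_alone, "stress_combined": s_comb,
                     "stress_extra": s_comb - s_alone, "censored": censored})
    audit = pd.DataFrame(rows)
    usable_doses = audit.loc[~audit["censored"], "dose"].to_numpy()
    if usable_doses.size == 0:
        raise DomainError(
            f"every tested dose is saturated around EC50={ec50:.4g}; the "
            "added stress is not resolvable from this dose grid")
    below = usable_doses[usable_doses < ec50]
    above = usable_doses[usable_doses > ec50]
    chosen = np.concatenate([below[-window:] if window else below[:0],
                             usable_doses[usable_doses == ec50],
                             above[:window] if window else above[:0]])
    if chosen.size == 0:
        # EC50 fell outside the resolvable range; use the nearest doses
        order = np.argsort(np.abs(np.log(usable_doses) - np.log(ec50)))
        chosen = usable_doses[order[:max(2 * window, 1)]]
    audit["in_window"] = audit["dose"].isin(chosen)
    raw = float(audit.loc[audit["in_window"], "stress_extra"].mean())
    if raw < 0:
        logger.warning(
            "negative inferred General-Stress (%.4g) floored at 0: combined "
            "survival exceeds the alone fit in the window", raw)
    return GeneralStressEstimate(max(raw, 0.0), audit, tuple(chosen.tolist()))


def sam_predict_curve(tox_curve, s_env, dist) -> Callable:
    """Predicted survival-over-dose under an added General-Stress ``s_env``:
    N_pred(t) = N( S(N_tox(t)) + s_env ).  With s_env = 0 this is the
    unmodified toxicant survival curve."""
    s_env = _as_value(s_env)
    if s_env < 0:
        raise DomainError("s_env must be >= 0")

    def predicted(dose):
        surv_tox = 1.0 - np.asarray(tox_curve.effect_at(dose), dtype=float)
        return dist.survival(dist.stress(surv_tox) + s_env)

    return predicted


def sam_predict_ec50(tox_curve, s_env, dist, relative_to: str = "stressed_control",
                     rtol: float = 1e-12) -> float:
    """SAM-predicted EC50 under an added General-Stress.

    The effect criterion is the midpoint of the predicted curve's own range
    between its stressed control (dose 0) and its high-dose plateau
    (``relative_to='stressed_control'``, default), or the midpoint of the
    unstressed curve's range (``relative_to='unstressed_control'``).  With
    ``s_env = 0`` both coincide with the unmodified EC50.
    """
    s_env = _as_value(s_env)
    curve = sam_predict_curve(tox_curve, s_env, dist)
    n0 = float(curve(0.0))
    b, c, d, e, f = tox_curve.params
    n_inf = float(dist.survival(dist.stress(1.0 - d) + s_env))
    if relative_to == "stressed_control":
        target = 0.5 * (n0 + n_inf)
    elif relative_to == "unstressed_control":
        target = 0.5 * ((1.0 - c) + (1.0 - d))
        if n0 <= target:
            raise DomainError(
                "stressed control survival is already at or below the "
                "effect criterion of the unstressed range")
    else:
        raise ValueError(f"unknown relative_to {relative_to!r}")
    if not n0 > target:
        raise DomainError("stressed control already below the effect criterion")
    lo, hi = np.log(e) - 60.0, np.log(e) + 60.0
    root = optimize.brentq(lambda lt: float(curve(np.exp(lt))) - target,
                           lo, hi, xtol=rtol, rtol=1e-15)
    return float(np.exp(root))
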