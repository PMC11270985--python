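"""Combined-effect null models (effect addition, concentration addition) and
model-deviation-ratio (MDR) synergy quantification.

Effect addition (EA, Bliss independence) combines the effects of
dissimilarly acting stressors as :math:`E_{mix} = 1 - \\prod_i (1 - E_i)`.
Concentration addition (CA, Loewe) combines similarly acting toxicants on
the dose scale: :math:`ECx_{mix} = (\\sum_i p_i / ECx_i)^{-1}` with
:math:`p_i` the relative concentration fractions.

The MDR is the predicted EC50 divided by the observed EC50.  MDR < 0.5 is
read as antagonism, 0.5-1 as additivity, 1-2 as weak synergism and > 2 as
strong synergism.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

from .exceptions import DomainError, ValidationError
from .io import report_round

_FRACTION_TOL = 1e-9


@dataclasses.dataclass(frozen=True)
class MixtureComponent:
    """One toxicant in a CA mixture: its relative concentration fraction and
    its own ECx."""

    name: str
    fraction_p: float
    ecx: float

    def __post_init__(self):
        if not 0.0 <= self.fraction_p <= 1.0:
            raise ValidationError("fraction_p must lie in [0, 1]")
        if not self.ecx > 0:
            raise DomainError(f"component {self.name}: ECx must be > 0")


@dataclasses.dataclass(frozen=True)
class PredictionRecord:
    """One (condition, null model) comparison row.

    ``condition`` is (population, temperature °C, prochloraz µg/L);
    ``design`` names the comparison layout the row came from.
    """

    condition: tuple
    design: str
    model: str
    observed_ec50: float
    predicted_ec50: float
    mdr: float
    classification: str


def ea_combined_effect(effects: Iterable[float]) -> float:
    """Bliss independent-action joint effect, 1 - prod(1 - E_i).

    Commutative; a singleton returns its own effect; adding a zero-effect
    component is a no-op.
    """
    effects = list(effects)
    total = 1.0
    for e in effects:
        if not 0.0 <= e <= 1.0:
            raise DomainError(f"effect {e} outside [0, 1]")
        total *= 1.0 - e
    return 1.0 - total


def ca_combined_ecx(components: Sequence[MixtureComponent]) -> float:
    """Loewe concentration-addition mixture ECx: the reciprocal of the
    fraction-weighted sum of reciprocal component ECx values."""
    if not components:
        raise ValidationError("need at least one mixture component")
    fractions = sum(c.fraction_p for c in components)
    if abs(fractions - 1.0) > _FRACTION_TOL:
        raise ValidationError(
            f"mixture fractions must sum to 1 (got {fractions!r})")
    denom = sum(c.fraction_p / c.ecx for c in components)
    if denom <= 0:
        raise DomainError("degenerate mixture: no component carries mass")
    return 1.0 / denom


def predict_ec50_with_costressor(model: str, tox_curve, costressor_effect: float,
                                 rtol: float = 1e-12) -> float:
    """Predicted EC50 of the primary toxicant in the presence of a co-stressor
    exerting a fixed marginal effect, under EA or CA.

    EA: the dose at which the Bliss-combined effect, rescaled to the combined
    control (co-stressor alone) and combined maximum, crosses its midpoint.
    For a binary mixture this rescaling makes the prediction coincide with
    the unmodified EC50 — the co-stressor shifts both the control and the
    response floor equally, which is exactly the paper-style comparison of a
    treatment against its own co-stressed control.

    CA: the co-stressor's effect is converted to an equivalent dose of the
    primary toxicant through the inverse of its fitted curve and subtracted
    on the Loewe isobole, EC50_pred = EC50 - dose_equivalent.

    Under CA a co-stressor whose own effect reaches 50% of the response
    range has a dose equivalent at or beyond the EC50, so no finite
    prediction exists and :class:`DomainError` is raised; under EA the
    rescaled criterion keeps a finite root for any co-stressor effect
    below 1.
    """
    if not 0.0 <= costressor_effect < 1.0:
        raise DomainError("costressor_effect must lie in [0, 1)")
    ec50 = tox_curve.ec(50.0, ci="none", relative=True).dose
    if costressor_effect == 0.0:
        return float(ec50)
    model = model.upper()
    if model == "EA":
        b, c, d, e, f = tox_curve.params

        def combined(dose):
            return ea_combined_effect([tox_curve.effect_at(float(dose)),
                                       costressor_effect])

        low = combined(0.0)
        high = ea_combined_effect([d, costressor_effect])
        target = low + 0.5 * (high - low)
        lo, hi = np.log(ec50) - 60.0, np.log(ec50) + 60.0
        root = optimize.brentq(lambda lt: combined(np.exp(lt)) - target,
                               lo, hi, xtol=rtol, rtol=1e-15)
        return float(np.exp(root))
    if model == "CA":
        if costressor_effect >= 0.5:
            raise DomainError(
                "co-stressor effect >= 50%: its dose equivalent reaches the "
                "EC50 and no finite CA prediction exists")
        dose_eq = tox_curve.ec(100.0 * costressor_effect, ci="none",
                               relative=True).dose
        pred = ec50 - dose_eq
        if pred <= 0:
            raise DomainError(
                "co-stressor dose equivalent exceeds the EC50; no finite "
                "CA prediction")
        return float(pred)
    raise ValueError(f"unknown null model {model!r}; use 'EA' or 'CA'")


def mdr(predicted_ec50: float, observed_ec50: float) -> float:
    """Model deviation ratio, predicted/observed; raw, unrounded."""
    if not (predicted_ec50 > 0 and observed_ec50 > 0):
        raise DomainError("MDR needs strictly positive EC50s")
    return float(predicted_ec50) / float(observed_ec50)


def classify_mdr(value: float) -> str:
    """Partition of the MDR axis: <0.5 antagonism, [0.5, 1] additive,
    (1, 2] weak synergism, >2 strong synergism."""
    if not value > 0:
        raise DomainError("MDR must be > 0")
    if value < 0.5:
        return "antagonism"
    if value <= 1.0:
        return "additive"
    if value <= 2.0:
        return "weak_synergism"
    return "strong_synergism"


def mdr_rounded(predicted_ec50: float, observed_ec50: float,
                decimals: int = 2) -> float:
    """Report-layer MDR: round-half-even at ``decimals`` places."""
    return report_round(mdr(predicted_ec50, observed_ec50), decimals)
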