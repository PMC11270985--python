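"""Five-parameter log-logistic (LL5) dose-response modelling of immobility.

The mean model for the immobile fraction at dose :math:`t` is

.. math::

    E(t) = c + \\frac{d - c}{\\bigl(1 + \\exp\\{b\\,[\\ln e - \\ln t]\\}\\bigr)^f}

with slope :math:`b > 0` (immobility nondecreasing in dose), lower asymptote
:math:`c` (background immobility, reached as :math:`t \\to 0`), upper
asymptote :math:`d`, inflection dose :math:`e` (µg/L) and asymmetry
:math:`f > 0`.  With :math:`f = 1` the curve is symmetric on the log-dose
axis and :math:`e` is the (relative) EC50.  The control dose 0 sits on the
lower asymptote and is never log-transformed.

Counts of immobile animals are modelled as binomial draws per treatment and
the parameters estimated by maximum likelihood; with a dozen animals per
treatment the Gaussian approximation behind least squares is poor, so the
binomial likelihood is the default (a least-squares fallback is provided for
cross-checks against conventional dose-response software).

Confidence intervals for ECx are computed by profile likelihood by default
(the model is reparameterised so that log-ECx is itself a parameter), with a
delta-method alternative on the log-dose scale.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

from .exceptions import DomainError, FitError, ValidationError

_EPS = 1e-10
_CHI2_95 = float(stats.chi2.ppf(0.95, 1))

#: box bounds on the internal parameter vector
#: theta = (log b, logit c, logit r, log ecx, log f), d = c + (1-c) r.
#: The slope and asymmetry boxes span the biologically plausible range;
#: an unbounded slope lets coarse dose grids collapse to step fits whose
#: EC50 snaps to the edge of a dose gap.
_BOUNDS = [
    (np.log(0.1), np.log(10.0)),
    (-12.0, 12.0),
    (-12.0, 12.0),
    (None, None),
    (np.log(0.2), np.log(5.0)),
]

#: deterministic jitter ladder applied to the starting values; no RNG in fitting
_JITTER = (
    np.zeros(5),
    np.array([0.3, 0.0, 0.0, 0.3, 0.0]),
    np.array([-0.3, 0.0, 0.0, -0.3, 0.5]),
    np.array([0.5, -1.0, 1.0, 0.0, -0.5]),
)


def ll5_effect(dose, b, c, d, e, f):
    """Evaluate the LL5 immobile fraction at ``dose`` (scalar or array).

    Dose 0 maps to the lower asymptote ``c``; negative doses are a domain
    error.  Values lie in [c, d] and are nondecreasing in dose for b > 0.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise DomainError("dose must be >= 0")
    scalar = dose.ndim == 0
    dose = np.atleast_1d(dose)
    out = np.full(dose.shape, float(c))
    pos = dose > 0
    z = b * (np.log(e) - np.log(dose[pos]))
    # (1+exp(z))^-f computed in log space to dodge overflow
    out[pos] = c + (d - c) * np.exp(-f * np.logaddexp(0.0, z))
    return float(out[0]) if scalar else out


def _ecx_offset(x: float, f: float) -> float:
    """log(e) - log(ECx_relative) = log((100/x)^(1/f) - 1) / b without the 1/b."""
    return float(np.log((100.0 / x) ** (1.0 / f) - 1.0))


def _unpack(theta, x):
    lb, zc, zr, lt, lf = theta
    b = float(np.exp(lb))
    c = float(special.expit(zc))
    d = c + (1.0 - c) * float(special.expit(zr))
    f = float(np.exp(lf))
    e = float(np.exp(np.clip(lt + _ecx_offset(x, f) / b, -700.0, 700.0)))
    return b, c, d, e, f


@dataclasses.dataclass(frozen=True)
class ECEstimate:
    """An ECx point estimate with a confidence interval (all µg/L)."""

    level_x: float
    dose: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not self.dose > 0:
            raise ValidationError("ECx dose must be > 0")


@dataclasses.dataclass(frozen=True)
class LL5Curve:
    """A bare LL5 parameter curve (no data attached).

    Duck-type compatible with :class:`LogLogistic5Results` wherever only the
    curve itself is needed (forward evaluation, ECx extraction, SAM and
    null-model prediction); confidence intervals are unavailable.
    """

    slope_b: float
    lower_c: float
    upper_d: float
    inflection_e: float
    asymmetry_f: float

    def __post_init__(self):
        if not (0.0 <= self.lower_c <= self.upper_d <= 1.0):
            raise ValidationError("need 0 <= lower_c <= upper_d <= 1")
        if self.inflection_e <= 0 or self.asymmetry_f <= 0 or self.slope_b <= 0:
            raise ValidationError("slope_b, inflection_e, asymmetry_f must be > 0")

    @property
    def params(self) -> pd.Series:
        return pd.Series(dataclasses.asdict(self))

    def effect_at(self, dose):
        return ll5_effect(dose, self.slope_b, self.lower_c, self.upper_d,
                          self.inflection_e, self.asymmetry_f)

    predict = effect_at

    def survival_at(self, dose):
        return 1.0 - np.asarray(self.effect_at(dose))

    def ec(self, x: float = 50.0, ci: str = "none",
           relative: bool = True) -> ECEstimate:
        """Closed-form ECx of the parameter curve (no interval)."""
        if not 0.0 < x < 100.0:
            raise DomainError("effect level x must be strictly inside (0, 100)")
        if ci != "none":
            raise ValueError("a bare LL5Curve carries no uncertainty")
        c, d, f = self.lower_c, self.upper_d, self.asymmetry_f
        if relative:
            ratio = 100.0 / x
        else:
            target = x / 100.0
            if not c < target < d:
                raise DomainError(
                    f"absolute effect level {x}% outside ({100 * c:.1f}%, "
                    f"{100 * d:.1f}%)")
            ratio = (d - c) / (target - c)
        lt = (np.log(self.inflection_e)
              - np.log(ratio ** (1.0 / f) - 1.0) / self.slope_b)
        dose = float(np.exp(lt))
        return ECEstimate(x, dose, dose, dose)


class LogLogistic5:
    """Binomial LL5 dose-response model for one experimental condition.

    Parameters
    ----------
    dose
        Test concentrations (µg/L), including the control at 0.
    immobile
        Immobile counts per row.
    exposed
        Exposed counts per row.
    x
        The ECx level used for the internal parameterisation (default 50);
        log-ECx at this level is a free parameter, which makes its profile
        likelihood direct.

    Replicate rows sharing a dose are pooled, so fits are invariant to row
    order and to splitting a treatment's count across rows.
    """

    def __init__(self, dose, immobile, exposed, x: float = 50.0):
        dose = np.asarray(dose, dtype=float)
        immobile = np.asarray(immobile, dtype=float)
        exposed = np.asarray(exposed, dtype=float)
        if dose.shape != immobile.shape or dose.shape != exposed.shape:
            raise ValidationError("dose, immobile, exposed must share a shape")
        if np.any(dose < 0):
            raise ValidationError("doses must be >= 0")
        if np.any(exposed <= 0) or np.any(immobile < 0) or np.any(immobile > exposed):
            raise ValidationError("need 0 <= immobile <= exposed and exposed > 0")
        # pool replicates: aggregate counts per distinct dose
        frame = (pd.DataFrame({"dose": dose, "k": immobile, "n": exposed})
                 .groupby("dose", sort=True).sum().reset_index())
        self.dose = frame["dose"].to_numpy()
        self.immobile = frame["k"].to_numpy()
        self.exposed = frame["n"].to_numpy()
        self.x = float(x)
        if len(self.dose) < 5:
            raise ValidationError("need >= 5 distinct doses to fit 5 parameters")
        if self.dose[0] != 0.0:
            raise ValidationError("a control (dose 0) treatment is required")

    @classmethod
    def from_table(cls, table: pd.DataFrame, x: float = 50.0) -> "LogLogistic5":
        """Build from a (subset of a) trial table for a single condition."""
        return cls(table["clothianidin_conc"].to_numpy(),
                   table["n_immobile"].to_numpy(),
                   table["n_exposed"].to_numpy(), x=x)

    # -- likelihood ---------------------------------------------------------

    def _effect(self, theta, dose):
        b, c, d, e, f = _unpack(theta, self.x)
        return ll5_effect(dose, b, c, d, e, f)

    def nloglik(self, theta) -> float:
        p = np.clip(self._effect(theta, self.dose), _EPS, 1.0 - _EPS)
        k, n = self.immobile, self.exposed
        return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())

    def _nss(self, theta) -> float:
        """Least-squares objective on proportions (cross-check fallback)."""
        p = self._effect(theta, self.dose)
        return float(((self.immobile / self.exposed - p) ** 2).sum())

    def start_values(self) -> np.ndarray:
        """Deterministic starts from a logit-linear regression on proportions."""
        k, n, dose = self.immobile, self.exposed, self.dose
        p = (k + 0.5) / (n + 1.0)
        pos = dose > 0
        c0 = min(max(float(p[~pos].mean()), 1e-3), 0.4)
        d0 = min(max(float(p.max()), c0 + 0.1), 0.999)
        pr = np.clip((p[pos] - c0) / max(d0 - c0, 1e-6), 1e-3, 1 - 1e-3)
        y = special.logit(pr)
        xs = np.log(dose[pos])
        A = np.vstack([xs, np.ones_like(xs)]).T
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        b0 = max(min(float(coef[0]), 20.0), 0.2)
        if abs(coef[0]) > 1e-8:
            e0 = float(np.exp(-coef[1] / coef[0]))
        else:
            e0 = float(np.exp(np.median(xs)))
        e0 = min(max(e0, float(dose[pos].min()) / 10), float(dose[pos].max()) * 10)
        r0 = min(max((d0 - c0) / (1 - c0), 1e-3), 1 - 1e-3)
        # log ECx(level x) start: with f0=1, offset = log((100/x) - 1)/b0
        lt0 = np.log(e0) - _ecx_offset(self.x, 1.0) / b0
        return np.array([np.log(b0), special.logit(c0), special.logit(r0), lt0, 0.0])

    def _check_degenerate(self):
        frac = self.immobile / self.exposed
        if np.all((frac == 0.0) | (frac == 1.0)):
            raise FitError(
                "all-or-nothing response at every dose: the slope is not "
                "identifiable; use a reduced (fixed-asymptote, fixed-slope) "
                "model or pool with adjacent conditions",
                diagnostics={"fractions": frac.tolist(), "dose": self.dose.tolist()},
            )

    def fit(self, method: str = "ml") -> "LogLogistic5Results":
        """Maximise the binomial likelihood (or minimise squared error with
        ``method='ls'``) over a deterministic multistart ladder."""
        self._check_degenerate()
        objective = self.nloglik if method == "ml" else self._nss
        th0 = self.start_values()
        best = None
        for jit in _JITTER:
            res = optimize.minimize(objective, th0 + jit, method="L-BFGS-B",
                                    bounds=_BOUNDS, options={"maxiter": 500})
            if best is None or res.fun < best.fun - 1e-9:
                best = res
        if best is None or not np.all(np.isfinite(best.x)):
            raise FitError("LL5 optimisation failed to converge", diagnostics=best)
        boundary = self._boundary_flags(best.x)
        return LogLogistic5Results(self, best.x, -best.fun, best, method, boundary)

    def _boundary_flags(self, theta) -> dict:
        flags = {}
        names = ("slope_b", "lower_c", "upper_d", "log_ecx", "asymmetry_f")
        for i, (lo, hi) in enumerate(_BOUNDS):
            at = (lo is not None and theta[i] < lo + 1e-6) or \
                 (hi is not None and theta[i] > hi - 1e-6)
            if at:
                flags[names[i]] = float(theta[i])
        return flags


class LogLogistic5Results:
    """Fitted LL5 curve: parameter estimates, likelihood, ECx extraction."""

    def __init__(self, model, theta, llf, optim, method, boundary):
        self.model = model
        self._theta = np.asarray(theta, dtype=float)
        self.llf = float(llf)
        self.optim = optim
        self.method = method
        self.boundary = boundary
        b, c, d, e, f = _unpack(self._theta, model.x)
        self.params = pd.Series(
            {"slope_b": b, "lower_c": c, "upper_d": d,
             "inflection_e": e, "asymmetry_f": f})
        self.nobs = int(model.exposed.sum())
        self._cov_internal = None

    # -- curve evaluation ---------------------------------------------------

    def effect_at(self, dose):
        """Immobile fraction at ``dose``; dose 0 returns the lower asymptote."""
        b, c, d, e, f = self.params
        return ll5_effect(dose, b, c, d, e, f)

    def survival_at(self, dose):
        """Mobility (survival analogue) = 1 - immobile fraction."""
        return 1.0 - np.asarray(self.effect_at(dose))

    predict = effect_at

    # -- covariance ---------------------------------------------------------

    def cov_params(self) -> pd.DataFrame:
        """Delta-method covariance of (b, c, d, e, f) from the internal Hessian."""
        cov_int = self._internal_cov()
        jac = np.empty((5, 5))
        h = 1e-6
        for j in range(5):
            step = np.zeros(5)
            step[j] = h
            up = np.array(_unpack(self._theta + step, self.model.x))
            dn = np.array(_unpack(self._theta - step, self.model.x))
            jac[:, j] = (up - dn) / (2 * h)
        cov = jac @ cov_int @ jac.T
        names = list(self.params.index)
        return pd.DataFrame(cov, index=names, columns=names)

    def _internal_cov(self) -> np.ndarray:
        if self._cov_internal is None:
            H = self._hessian()
            self._cov_internal = np.linalg.pinv(H, rcond=1e-10, hermitian=True)
        return self._cov_internal

    def _hessian(self) -> np.ndarray:
        th = self._theta
        f0 = self.model.nloglik
        h = 1e-4
        H = np.empty((5, 5))
        for i in range(5):
            for j in range(i, 5):
                ei = np.zeros(5); ei[i] = h
                ej = np.zeros(5); ej[j] = h
                val = (f0(th + ei + ej) - f0(th + ei - ej)
                       - f0(th - ei + ej) + f0(th - ei - ej)) / (4 * h * h)
                H[i, j] = H[j, i] = val
        return H

    # -- ECx ----------------------------------------------------------------

    def _log_ecx(self, theta, x, relative=True) -> float:
        b, c, d, e, f = _unpack(theta, self.model.x)
        if relative:
            ratio = 100.0 / x
        else:
            target = x / 100.0
            if not c < target < d:
                raise DomainError(
                    f"absolute effect level {x}% outside the achievable range "
                    f"({100 * c:.1f}%, {100 * d:.1f}%)")
            ratio = (d - c) / (target - c)
        return float(np.log(e) - np.log(ratio ** (1.0 / f) - 1.0) / b)

    def ec(self, x: float = 50.0, ci: str = "profile",
           relative: bool = True) -> ECEstimate:
        """ECx: the dose at x% effect, rescaled between the asymptotes when
        ``relative`` (default) or on the absolute effect scale otherwise.

        ``ci`` is ``"profile"`` (profile likelihood, default), ``"delta"``
        (delta method on log-dose) or ``"none"``.
        """
        if not 0.0 < x < 100.0:
            raise DomainError("effect level x must be strictly inside (0, 100)")
        lt = self._log_ecx(self._theta, x, relative)
        dose = float(np.exp(lt))
        if ci == "none":
            return ECEstimate(x, dose, dose, dose)
        if ci == "delta":
            g = optimize.approx_fprime(
                self._theta, lambda th: self._log_ecx(th, x, relative), 1e-6)
            var = float(g @ self._internal_cov() @ g)
            sd = np.sqrt(max(var, 0.0))
            return ECEstimate(x, dose,
                              float(np.exp(lt - 1.959963984540054 * sd)),
                              float(np.exp(lt + 1.959963984540054 * sd)))
        if ci == "profile":
            lo, hi = self._profile_ci(x, relative)
            return ECEstimate(x, dose, float(np.exp(lo)), float(np.exp(hi)))
        raise ValueError(f"unknown ci method {ci!r}")

    def _profile_ci(self, x, relative):
        """95% profile-likelihood interval for log-ECx.

        Exact only for the model's own parameterisation level (x == model.x
        and relative); other levels are profiled through a shifted internal
        parameter, which is equivalent because the map is monotone in lt.
        """
        shift = self._log_ecx(self._theta, x, relative) - self._theta[3]
        llmax = self.llf
        mdl = self.model

        def profiled_ll(lt_target):
            th0 = self._theta.copy()
            th0[3] = lt_target - shift
            bounds = list(_BOUNDS)
            bounds[3] = (th0[3], th0[3])
            res = optimize.minimize(mdl.nloglik, th0, method="L-BFGS-B",
                                    bounds=bounds, options={"maxiter": 300})
            return -res.fun

        lt_hat = self._log_ecx(self._theta, x, relative)

        def deviance_gap(lt):
            return 2.0 * (llmax - profiled_ll(lt)) - _CHI2_95

        out = []
        for sign in (-1.0, 1.0):
            step = 0.25
            inner = lt_hat
            bracket = None
            for i in range(80):
                probe = lt_hat + sign * step * (i + 1)
                if deviance_gap(probe) > 0:
                    bracket = (min(inner, probe), max(inner, probe))
                    break
                inner = probe
            if bracket is None:
                out.append(sign * np.inf)
            else:
                out.append(float(optimize.brentq(deviance_gap, *bracket, xtol=1e-5)))
        return out[0], out[1]

    # -- presentation -------------------------------------------------------

    def summary(self) -> str:
        ec = self.ec(50.0, ci="delta")
        lines = [
            "Five-parameter log-logistic dose-response (binomial ML)"
            if self.method == "ml" else
            "Five-parameter log-logistic dose-response (least squares)",
            f"  n observations (animals): {self.nobs}",
            f"  log-likelihood: {self.llf:.3f}",
        ]
        for name, val in self.params.items():
            lines.append(f"  {name:<14s} {val:12.4f}")
        lines.append(f"  EC50 (relative) {ec.dose:10.4f}  "
                     f"[{ec.ci_low:.4f}, {ec.ci_high:.4f}] (delta, 95%)")
        if self.boundary:
            lines.append(f"  boundary flags: {self.boundary}")
        return "\n".join(lines)

    def plot(self, ax=None, n_grid: int = 200):
        """Plot observed fractions and the fitted curve (log-dose axis)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        dose, k, n = self.model.dose, self.model.immobile, self.model.exposed
        pos = dose > 0
        lo, hi = dose[pos].min(), dose[pos].max()
        grid = np.geomspace(lo / 10, hi * 10, n_grid)
        ax.plot(grid, self.effect_at(grid), "-", label="LL5 fit")
        ax.plot(dose[pos], (k / n)[pos], "o", label="observed")
        ax.axhline(float(k[~pos] / n[~pos]) if (~pos).any() else np.nan,
                   ls=":", lw=0.8, color="grey")
        ax.set_xscale("log")
        ax.set_xlabel("dose (µg/L)")
        ax.set_ylabel("immobile fraction")
        ax.legend()
        return ax


# -- spec-surface wrappers ---------------------------------------------------

def fit_ll5(table: pd.DataFrame, method: str = "ml") -> LogLogistic5Results:
    """Fit the LL5 model to a trial-table subset for one condition."""
    return LogLogistic5.from_table(table).fit(method=method)


def ec_x(fit: LogLogistic5Results, x: float, ci: str = "profile",
         relative: bool = True) -> ECEstimate:
    """Extract ECx (µg/L) with a confidence interval from a fitted curve."""
    return fit.ec(x, ci=ci, relative=relative)


def effect_at(fit: LogLogistic5Results, dose):
    """Forward-evaluate the fitted immobile fraction at ``dose``."""
    return fit.effect_at(dose)
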