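"""Single-drug dose-response fitting and clinically capped dose selection.

Viability (% of vehicle control) against dose is described by the
four-parameter logistic (4PL)::

    y(d) = bottom + (top - bottom) / (1 + (d / ec50)^hill)

with ``hill > 0`` for an inhibitor (viability falls with dose).  The
screening doses fed into the combination design are deliberately low:
dose 2 is the ED20 (20% inhibition) and dose 1 is half of it — and dose 2
is additionally capped at the plasma concentration limit (PCL), the
time-averaged clinically attainable plasma concentration AUC_0-24h / 24 h.
Capping keeps the screen clinically relevant at the price of only the
strongest interactions remaining detectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

from .errors import DoseError

__all__ = [
    "DoseResponseFit",
    "PKSummary",
    "four_param_logistic",
    "fit_four_param_logistic",
    "effective_dose",
    "plasma_concentration_limit",
    "select_screen_doses",
    "auc_trapezoid",
]


@dataclass(frozen=True)
class DoseResponseFit:
    """Fitted 4PL parameters with per-point residuals."""

    top: float
    bottom: float
    ec50: float
    hill: float
    doses: np.ndarray
    responses: np.ndarray
    residuals: np.ndarray
    no_effect: bool = False  # flat-curve flag: fit is a boundary/degenerate one

    def predict(self, dose):
        return four_param_logistic(np.asarray(dose, dtype=float), self.top, self.bottom, self.ec50, self.hill)


@dataclass(frozen=True)
class PKSummary:
    """Trapezoidal AUC and C_max over an observed sampling window."""

    auc: float
    c_max: float
    times: np.ndarray
    concentrations: np.ndarray


def four_param_logistic(dose, top, bottom, ec50, hill):
    dose = np.asarray(dose, dtype=float)
    return bottom + (top - bottom) / (1.0 + (dose / ec50) ** hill)


def fit_four_param_logistic(doses, responses) -> DoseResponseFit:
    """Least-squares 4PL fit of viability (% CTRL) against dose.

    Requires at least 4 distinct positive doses.  A flat response is
    returned flagged ``no_effect`` (constant fit) rather than silently
    producing meaningless curve parameters.
    """
    d = np.asarray(doses, dtype=float).ravel()
    y = np.asarray(responses, dtype=float).ravel()
    if len(d) != len(y):
        raise DoseError("doses and responses differ in length")
    if (d <= 0).any():
        raise DoseError("doses must be strictly positive (control is implicit)")
    if len(np.unique(d)) < 4:
        raise DoseError("at least 4 distinct doses are required for a 4PL fit")
    spread = float(y.max() - y.min())
    if spread < 1e-6 * max(abs(y).max(), 1.0):
        flat = float(y.mean())
        return DoseResponseFit(
            top=flat, bottom=flat, ec50=float(np.median(d)), hill=1.0,
            doses=d, responses=y, residuals=y - flat, no_effect=True,
        )
    top0, bottom0 = float(y.max()), float(y.min())
    ec50_0 = float(np.exp(np.mean(np.log(d))))
    p0 = (top0, bottom0, ec50_0, 1.0)
    bounds = ([-np.inf, -np.inf, 1e-12, 1e-3], [np.inf, np.inf, np.inf, 20.0])
    try:
        popt, _ = scipy.optimize.curve_fit(
            lambda dd, t, b, e, h: four_param_logistic(dd, t, b, e, h),
            d, y, p0=p0, bounds=bounds, maxfev=20000,
        )
    except RuntimeError as exc:
        raise DoseError(f"4PL fit did not converge: {exc}") from exc
    top, bottom, ec50, hill = (float(v) for v in popt)
    resid = y - four_param_logistic(d, top, bottom, ec50, hill)
    no_effect = abs(top - bottom) < 1e-6 * max(abs(top), 1.0)
    return DoseResponseFit(
        top=top, bottom=bottom, ec50=ec50, hill=hill,
        doses=d, responses=y, residuals=resid, no_effect=no_effect,
    )


def effective_dose(fit: DoseResponseFit, inhibition_level: float) -> float:
    """Dose producing a given inhibition of control viability (ED10, ED20).

    The ED_L is the dose at which viability drops to top * (1 - L), i.e.
    L is inhibition relative to the untreated plateau, matching the usual
    reading of ED20 as "20% inhibition".  If the fitted bottom plateau
    sits above that target (maximum inhibition below L) the ED is not
    attainable and an error is raised.  On a full-span curve
    (bottom = 0) the ED50 coincides with the EC50.
    """
    if not (0 < inhibition_level < 1):
        raise DoseError("inhibition level must be in (0, 1)")
    if fit.no_effect or abs(fit.top - fit.bottom) < 1e-12:
        raise DoseError("ED not attainable: flat (no-effect) dose-response curve")
    if fit.hill == 0:
        raise DoseError("ED not attainable: zero hill slope")
    target = fit.top * (1.0 - inhibition_level)
    if not (fit.bottom < target < fit.top):
        raise DoseError(
            f"ED not attainable: target viability {target:.3g} lies outside the "
            f"fitted range ({fit.bottom:.3g}, {fit.top:.3g})"
        )
    # bottom + (top-bottom)/(1+(d/e)^h) = target  =>  (d/e)^h = (top-target)/(target-bottom)
    ratio = (fit.top - target) / (target - fit.bottom)
    return float(fit.ec50 * ratio ** (1.0 / fit.hill))


def plasma_concentration_limit(
    auc_0_24: float, molecular_weight: float | None = None
) -> float:
    """PCL = AUC_0-24h / 24 h: the time-averaged plasma concentration.

    ``auc_0_24`` in ug*h/mL yields ug/mL; with a molecular weight
    (g/mol) the result is converted to mol/L.
    """
    if auc_0_24 <= 0:
        raise DoseError("AUC_0-24h must be positive")
    pcl_mass = auc_0_24 / 24.0  # ug/mL
    if molecular_weight is None:
        return pcl_mass
    if molecular_weight <= 0:
        raise DoseError("molecular weight must be positive")
    # ug/mL = mg/L; divide by g/mol to get mmol/L... careful:
    # 1 ug/mL = 1e-3 g/L; (1e-3 g/L) / (MW g/mol) = 1e-3/MW mol/L
    return pcl_mass * 1e-3 / molecular_weight


def select_screen_doses(
    fit: DoseResponseFit | None, pcl: float | None
) -> tuple[float, float]:
    """Screening doses: dose2 = min(ED20, PCL), dose1 = dose2 / 2.

    If the ED20 is unattainable (flat curve) the PCL alone sets dose2;
    without either, no dose can be chosen.
    """
    ed20 = None
    if fit is not None:
        try:
            ed20 = effective_dose(fit, 0.20)
        except DoseError:
            ed20 = None
    if ed20 is None and pcl is None:
        raise DoseError("ED20 unattainable and no plasma concentration limit given")
    if pcl is not None and pcl <= 0:
        raise DoseError("plasma concentration limit must be positive")
    if ed20 is None:
        dose2 = float(pcl)
    elif pcl is None:
        dose2 = float(ed20)
    else:
        dose2 = float(min(ed20, pcl))
    return dose2 / 2.0, dose2


def auc_trapezoid(times, concentrations) -> PKSummary:
    """Trapezoidal AUC over the observed interval, plus C_max.

    No extrapolation beyond the last sample; with the sparse clinical
    sampling (e.g. 2, 4, 8, 24 h) this is the conservative choice.
    """
    t = np.asarray(times, dtype=float).ravel()
    c = np.asarray(concentrations, dtype=float).ravel()
    if len(t) != len(c):
        raise DoseError("times and concentrations differ in length")
    if len(t) < 2:
        raise DoseError("at least 2 time points are required")
    if (np.diff(t) <= 0).any():
        raise DoseError("times must be strictly increasing")
    if (c < 0).any():
        raise DoseError("concentrations must be nonnegative")
    auc = float(np.trapezoid(c, t))
    return PKSummary(auc=auc, c_max=float(c.max()), times=t, concentrations=c)
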