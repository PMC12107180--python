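"""Dissociation constants from saturating binding curves.

Two assay geometries produce the same functional form.  A filter-binding
assay reads out bound radiolabel (cpm) versus protein concentration; a
microfluidic diffusional-sizing assay reads out the hydrodynamic radius
(nm) of a protein versus RNA concentration.  Both saturate as a
single-site isotherm

    y(x) = A + B / (1 + Kd / x) = A + B * x / (Kd + x),

whose inflection point in a semilog-x plot sits at x = Kd.  The fitters
return the baseline, amplitude and Kd with standard errors, and flag
degenerate fits (no resolvable amplitude, Kd pinned at a bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingFit",
    "binding_model",
    "fit_filter_binding",
    "fit_sizing_curve",
    "kd_fold_ratio",
]


@dataclass(frozen=True)
class BindingFit:
    """Fitted single-site isotherm parameters.

    ``baseline`` is the unbound-state signal (A, or Rh_free for sizing),
    ``amplitude`` the bound-minus-free difference (B), ``kd`` the
    dissociation constant in the units of x.  ``flagged`` marks fits
    whose Kd should not be trusted.
    """

    baseline: float
    amplitude: float
    kd: float
    baseline_err: float = np.nan
    amplitude_err: float = np.nan
    kd_err: float = np.nan
    rss: float = np.nan
    flagged: bool = False

    @property
    def plateau(self) -> float:
        """Saturated-state signal (A + B, or Rh_bound)."""
        return self.baseline + self.amplitude


def binding_model(x, baseline, amplitude, kd):
    """Single-site saturation isotherm y = A + B * x / (Kd + x)."""
    x = np.asarray(x, dtype=float)
    return baseline + amplitude * x / (kd + x)


def _fit(x: np.ndarray, y: np.ndarray, noise_floor_factor: float = 3.0) -> BindingFit:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 points to fit a binding curve")
    if np.any(x <= 0) or np.any(np.diff(x) <= 0):
        raise ValueError("x must be positive and strictly increasing")
    if x.max() / x.min() < 100:
        raise ValueError("x must span at least two decades")

    p0 = [float(y.min()), float(y.max() - y.min()),
          float(np.sqrt(x.min() * x.max()))]
    kd_lo, kd_hi = x.min() * 1e-3, x.max() * 1e3
    span = float(np.ptp(y)) or 1.0
    lo = [y.min() - 10 * span, -20 * span, kd_lo]
    hi = [y.max() + 10 * span, 20 * span, kd_hi]
    try:
        popt, pcov = curve_fit(binding_model, x, y, p0=p0, bounds=(lo, hi),
                               maxfev=5000)
        perr = np.sqrt(np.diag(pcov))
        converged = True
    except RuntimeError:
        popt, perr = np.array(p0), np.full(3, np.nan)
        converged = False

    resid = y - binding_model(x, *popt)
    rss = float(np.sum(resid**2))
    noise = float(np.std(resid, ddof=min(3, y.size - 1)))
    # a Kd far outside the sampled range is not constrained by the data
    kd_unidentified = not (x.min() / 3 <= popt[2] <= x.max() * 3)
    # plateaus indistinct: the modeled signal change over the sampled
    # range must rise above the noise floor
    span = abs(binding_model(x.max(), *popt) - binding_model(x.min(), *popt))
    indistinct = span < noise_floor_factor * noise
    flagged = (not converged) or kd_unidentified or indistinct
    return BindingFit(
        baseline=float(popt[0]), amplitude=float(popt[1]), kd=float(popt[2]),
        baseline_err=float(perr[0]), amplitude_err=float(perr[1]),
        kd_err=float(perr[2]), rss=rss, flagged=flagged,
    )


def fit_filter_binding(x, y) -> BindingFit:
    """Fit y = A + B / (1 + Kd / x) to a filter-binding signal curve.

    ``x`` is the titrated protein concentration, ``y`` the bound signal
    (e.g. cpm of retained radiolabeled RNA).
    """
    return _fit(x, y)


def fit_sizing_curve(x, y) -> BindingFit:
    """Fit the hydrodynamic-radius isotherm Rh(x) = Rh_free + dRh * x / (Kd + x).

    ``x`` is the ligand (RNA) concentration, ``y`` the measured
    hydrodynamic radius (nm).  The fitted Kd coincides with the
    inflection point of the curve in semilog-x.  Curves with
    indistinguishable plateaus (amplitude below three times the residual
    noise, e.g. a non-binding zinc-finger deletion) come back flagged
    and their Kd must not be reported.
    """
    return _fit(x, y)


def kd_fold_ratio(kd_a: float, kd_b: float, *, paper_style: bool = False) -> float:
    """Affinity fold ratio ``kd_a / kd_b``.

    With ``paper_style`` the ratio is rounded to the nearest integer
    fold, the convention for prose statements.
    """
    if kd_a <= 0 or kd_b <= 0:
        raise ValueError("dissociation constants must be positive")
    fold = kd_a / kd_b
    return float(round(fold)) if paper_style else fold
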