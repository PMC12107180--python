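"""Phase-diagram thermodynamics from per-droplet records.

A microfluidic phase-diagram experiment yields, per water-in-oil
droplet, the total concentrations of PGL-3 (uM), RNA (ng/uL) and MEX-5
(uM), a demixing probability, and the dilute-phase PGL-3 concentration.
This module turns such record tables into thermodynamic read-outs:

* the saturation concentration ``c_sat`` of PGL-3 versus MEX-5 at fixed
  RNA, with error bands from near-boundary droplets;
* dilute-phase concentration bands and the contour slope ``K``, a lower
  bound on the PGL-3:RNA tie-line component ratio;
* the response gradient ``R`` of the dilute phase and the Dominance
  ``1 - R``, the fraction of the free-energy change of phase separation
  attributable to PGL-3.

A deterministic intensity-heterogeneity classifier stands in for the
image classifier used upstream of such tables; precomputed ``p_demix``
columns are equally accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import curve_fit

__all__ = [
    "LogisticCalibration",
    "LinearCalibration",
    "classify_droplet",
    "calibrate_concentration",
    "dilute_phase_conc",
    "csat_dose_response",
    "assign_bands",
    "band_count",
    "contour_slope_K",
    "dominance",
]


@dataclass(frozen=True)
class LogisticCalibration:
    """Maps an intensity-heterogeneity score to a demixing probability."""

    midpoint: float = 0.15  # coefficient of variation at p = 0.5
    width: float = 0.03


def classify_droplet(
    crop: np.ndarray, calibration: LogisticCalibration | None = None
) -> float:
    """Condensate-presence probability from within-droplet heterogeneity.

    A droplet containing a condensate shows strong intensity
    heterogeneity; a homogeneous droplet only camera noise.  The
    coefficient of variation of the crop is mapped through a calibrated
    logistic onto [0, 1].
    """
    crop = np.asarray(crop, dtype=float)
    if crop.size == 0:
        raise ValueError("empty crop")
    cal = calibration or LogisticCalibration()
    mean = crop.mean()
    if mean <= 0:
        raise ValueError("crop mean must be positive (dark-corrected image)")
    cv = crop.std() / mean
    return float(1.0 / (1.0 + np.exp(-(cv - cal.midpoint) / cal.width)))


@dataclass(frozen=True)
class LinearCalibration:
    """Linear intensity -> concentration conversion for one channel."""

    slope: float
    intercept: float
    intensity_range: tuple[float, float]

    def __call__(self, intensity):
        i = np.asarray(intensity, dtype=float)
        lo, hi = self.intensity_range
        span = hi - lo
        if np.any(i < lo - 0.5 * span) or np.any(i > hi + 0.5 * span):
            warnings.warn(
                "intensity beyond 1.5x the calibration standard range",
                stacklevel=2,
            )
        out = self.slope * i + self.intercept
        return float(out) if out.ndim == 0 else out


def calibrate_concentration(
    intensities: np.ndarray, concentrations: np.ndarray
) -> LinearCalibration:
    """Fit a per-channel linear intensity-to-concentration calibration.

    Requires at least two standards with distinct intensities spanning
    the working range.
    """
    i = np.asarray(intensities, dtype=float)
    c = np.asarray(concentrations, dtype=float)
    if i.size < 2 or i.size != c.size:
        raise ValueError("need >= 2 paired calibration standards")
    if np.ptp(i) == 0:
        raise ValueError("calibration standards are not invertible "
                         "(equal intensities)")
    slope, intercept = np.polyfit(i, c, 1)
    return LinearCalibration(
        slope=float(slope), intercept=float(intercept),
        intensity_range=(float(i.min()), float(i.max())),
    )


def dilute_phase_conc(
    crop: np.ndarray,
    mask: np.ndarray,
    calibration: LinearCalibration,
    pixel_band: tuple[float, float] = (5.0, 25.0),
) -> float:
    """Dilute-phase concentration from the darkest pixels inside a droplet.

    Averages the pixels whose intensity lies between the ``pixel_band``
    percentiles (default 5th-25th) of the within-droplet distribution --
    a robust estimate unaffected by bright condensates -- then converts
    via the calibration.
    """
    crop = np.asarray(crop, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    vals = crop[mask]
    if vals.size < 20:
        raise ValueError("droplet mask too small for a stable percentile band")
    lo, hi = np.percentile(vals, pixel_band)
    band = vals[(vals >= lo) & (vals <= hi)]
    return float(calibration(band.mean()))


def _logistic_cdf(x, x0, s):
    return 1.0 / (1.0 + np.exp(-(x - x0) / s))


def csat_dose_response(
    records: pd.DataFrame,
    rna_level: float,
    rna_window: float = 0.2,
    mex5_levels: np.ndarray | None = None,
    mex5_tol: float = 1e-6,
    band_probs: tuple[float, float] = (0.46, 0.54),
) -> pd.DataFrame:
    """PGL-3 saturation concentration versus MEX-5 at fixed RNA.

    For each MEX-5 level, records with RNA within ``rna_window`` ng/uL of
    ``rna_level`` are selected and a monotone logistic is fit to
    ``p_demix`` along the PGL-3 axis; ``c_sat`` is the 0.5 crossing.  The
    error band is the standard deviation of the PGL-3 values of records
    whose demixing probability falls within ``band_probs``.

    Raises when the boundary is not bracketed within a window.
    """
    if mex5_levels is None:
        mex5_levels = np.unique(np.round(records["mex5_uM"].to_numpy(), 6))
    rows = []
    for level in np.atleast_1d(mex5_levels):
        sel = records[
            (np.abs(records["rna_ng_per_uL"] - rna_level) <= rna_window)
            & (np.abs(records["mex5_uM"] - level) <= mex5_tol)
        ]
        p = sel["p_demix"].to_numpy()
        x = sel["pgl3_uM"].to_numpy()
        if len(sel) < 3 or p.max() < 0.5 or p.min() > 0.5:
            raise ValueError(
                f"boundary out of range at MEX-5 = {level} uM: "
                "window does not bracket p_demix = 0.5"
            )
        x0_init = float(np.median(x[np.argsort(np.abs(p - 0.5))][: max(3, x.size // 5)]))
        try:
            popt, _ = curve_fit(
                _logistic_cdf, x, p, p0=[x0_init, 0.1],
                bounds=([x.min(), 1e-4], [x.max(), 10.0]), maxfev=2000,
            )
            csat = float(popt[0])
        except RuntimeError:
            csat = x0_init
        near = x[(p >= band_probs[0]) & (p <= band_probs[1])]
        band_sd = float(np.std(near, ddof=1)) if near.size >= 2 else np.nan
        rows.append({"mex5_uM": float(level), "csat_uM": csat,
                     "band_sd_uM": band_sd, "n_records": int(len(sel))})
    return pd.DataFrame(rows)


def assign_bands(values, spacing: float = 0.25) -> np.ndarray:
    """1-based band index for dilute-phase concentrations.

    Band k covers the half-open interval [(k-1) * spacing, k * spacing).
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("concentrations must be non-negative")
    return (np.floor(v / spacing) + 1).astype(int)


def band_count(axis_range: tuple[float, float] = (0.0, 2.0),
               spacing: float = 0.25) -> int:
    """Number of bands tiling a concentration axis at the given spacing."""
    lo, hi = axis_range
    if spacing <= 0 or hi <= lo:
        raise ValueError("invalid axis range or spacing")
    return int(np.ceil((hi - lo) / spacing - 1e-9))


def contour_slope_K(
    records: pd.DataFrame,
    dilute_window: tuple[float, float] = (1.55, 1.95),
    levels: np.ndarray | None = None,
    level_tol: float = 0.05,
) -> tuple[float, float]:
    """Mean slope K of dilute-phase PGL-3 contours, and its SD.

    For each contour level inside ``dilute_window`` (uM), demixed records
    (``p_demix >= 0.5``) whose dilute-phase PGL-3 lies within
    ``level_tol`` of the level are regressed: total PGL-3 on RNA.  K is
    the mean of the per-level slopes (uM per ng/uL) and the SD is taken
    across levels within the window.

    K lower-bounds the PGL-3:RNA tie-line component ratio; under RNA
    sequestration it shrinks because the free-RNA response to total RNA
    flattens.
    """
    if levels is None:
        levels = np.linspace(dilute_window[0] + level_tol,
                             dilute_window[1] - level_tol, 4)
    demixed = records[records["p_demix"] >= 0.5]
    slopes = []
    for level in np.atleast_1d(levels):
        sel = demixed[np.abs(demixed["pgl3_dilute_uM"] - level) <= level_tol]
        if len(sel) < 2 or sel["rna_ng_per_uL"].nunique() < 2:
            continue
        slope, _ = np.polyfit(sel["rna_ng_per_uL"].to_numpy(),
                              sel["pgl3_uM"].to_numpy(), 1)
        slopes.append(float(slope))
    if not slopes:
        raise ValueError("fewer than 2 demixed records on every contour level")
    k = float(np.mean(slopes))
    sd = float(np.std(slopes, ddof=1)) if len(slopes) > 1 else np.nan
    return k, sd


def dominance(
    records: pd.DataFrame,
    rna_level: float,
    rna_window: float = 5.0,
) -> dict[str, float]:
    """Response gradient R and Dominance = 1 - R at a fixed-RNA slice.

    In the demixed regime the dilute-phase PGL-3 concentration responds
    to the total with slope R (ordinary least squares); the smaller R,
    the more the dilute phase is buffered and the larger PGL-3's share of
    the free-energy change of phase separation.  Assumes a small
    condensate volume fraction.

    Returns a dict with ``R``, ``R_sd`` (standard error of the fitted
    slope), ``dominance`` and ``n``.
    """
    sel = records[
        (np.abs(records["rna_ng_per_uL"] - rna_level) <= rna_window)
        & (records["p_demix"] >= 0.5)
    ]
    if len(sel) < 3:
        raise ValueError("fewer than 3 demixed records in the RNA slice")
    fit = stats.linregress(sel["pgl3_uM"].to_numpy(),
                           sel["pgl3_dilute_uM"].to_numpy())
    r_grad = float(fit.slope)
    return {
        "R": r_grad,
        "R_sd": float(fit.stderr),
        "dominance": 1.0 - r_grad,
        "n": int(len(sel)),
    }
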