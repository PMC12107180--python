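"""Spherical-cap fitting of quantitative phase images.

A sessile liquid droplet on a coverslip is a truncated sphere.  In a
quantitative phase image the optical phase shift at a pixel is
proportional to the refractive-index difference between droplet and
medium times the height of droplet material traversed by the beam:

    dphi(x, y) = (2 pi / lambda) * dn * H_cap(x, y | R, xc, yc, Zeq) + phi0

where ``H_cap`` is the vertical chord through a sphere of radius ``R``
whose centre sits a height ``Zeq`` above the coverslip, and ``phi0`` is a
constant phase offset.  Fitting this forward model to each segmented
droplet yields ``dn`` per droplet; an adjusted-R^2 filter removes bad
fits, and fits of the same droplet across a z-stack are merged by
keeping the plane with the best fit quality.

An optional regularization term ``A(Zeq, R)`` may be supplied by the
user; by default it is identically zero with any constant absorbed into
``phi0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from skimage import measure
from skimage.filters import threshold_otsu

from .config import ADJ_R2_THRESHOLD, QPI_WAVELENGTH_NM

__all__ = [
    "PhaseImage",
    "DropletFit",
    "Roi",
    "cap_height",
    "phase_forward_model",
    "segment_phase_image",
    "fit_droplet",
    "filter_fits",
    "track_z",
    "summarize_dn",
]


@dataclass(frozen=True)
class PhaseImage:
    """A 2D optical phase-shift map (radians) with imaging metadata."""

    data: np.ndarray  # (ny, nx), radians
    wavelength_nm: float = QPI_WAVELENGTH_NM
    pixel_size_um: float = 0.1
    z_index: int = 0

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValueError("phase image must be 2D")
        if not np.all(np.isfinite(data)):
            raise ValueError("phase image must be finite")
        if self.wavelength_nm <= 0 or self.pixel_size_um <= 0:
            raise ValueError("wavelength and pixel size must be positive")


@dataclass(frozen=True)
class DropletFit:
    """Fitted spherical-cap parameters for one droplet in one plane.

    Attributes
    ----------
    dn : refractive-index difference (dimensionless)
    radius_um : droplet radius R (um)
    xc_um, yc_um : in-plane centroid (um, origin at the top-left pixel centre)
    zeq_um : height of the sphere centre above the coverslip (um)
    phi0 : constant phase offset (rad)
    adj_r2 : adjusted R^2 of the fit; NaN flags a failed fit
    """

    dn: float
    radius_um: float
    xc_um: float
    yc_um: float
    zeq_um: float
    phi0: float = 0.0
    adj_r2: float = np.nan
    z_index: int = 0
    flagged: bool = False


@dataclass(frozen=True)
class Roi:
    """A rectangular region of interest in pixel coordinates (half-open)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int
    touches_border: bool = False

    def slices(self) -> tuple[slice, slice]:
        return slice(self.row_min, self.row_max), slice(self.col_min, self.col_max)


def cap_height(x, y, fit: DropletFit):
    """Traversed height (um) through a coverslip-truncated sphere.

    The chord through the sphere at in-plane distance ``rho`` from the
    centroid has half-length ``s = sqrt(R^2 - rho^2)``; the coverslip at
    z = 0 clips the lower part, giving
    ``H = max(0, Zeq + s) - max(0, Zeq - s)`` inside the footprint and 0
    outside.  Total function; accepts scalars or arrays (um).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rho2 = (x - fit.xc_um) ** 2 + (y - fit.yc_um) ** 2
    s2 = fit.radius_um**2 - rho2
    s = np.sqrt(np.clip(s2, 0.0, None))
    h = np.maximum(0.0, fit.zeq_um + s) - np.maximum(0.0, fit.zeq_um - s)
    h = np.where(s2 < 0, 0.0, h)
    return float(h) if h.ndim == 0 else h


def phase_forward_model(
    x,
    y,
    fit: DropletFit,
    wavelength_nm: float = QPI_WAVELENGTH_NM,
    regularization: Callable[[float, float], float] | None = None,
):
    """Predicted phase shift (rad) at positions (x, y) in um."""
    lam_um = wavelength_nm * 1e-3
    dphi = (2.0 * np.pi / lam_um) * fit.dn * cap_height(x, y, fit) + fit.phi0
    if regularization is not None:
        dphi = dphi + regularization(fit.zeq_um, fit.radius_um)
    return dphi


def segment_phase_image(
    img: PhaseImage, min_area: int = 9, pad: int = 4
) -> list[Roi]:
    """Find candidate droplet regions by Otsu thresholding.

    Connected regions above the automatic threshold with at least
    ``min_area`` pixels become ROIs, each padded by ``pad`` pixels of
    surrounding background (clipped at the image border, in which case
    the ROI is flagged as border-touching).
    """
    data = img.data
    if data.size == 0 or np.ptp(data) == 0:
        return []
    thr = threshold_otsu(data)
    mask = data > thr
    labels = measure.label(mask)
    rois: list[Roi] = []
    for region in measure.regionprops(labels):
        if region.area < min_area:
            continue
        r0, c0, r1, c1 = region.bbox
        touches = (
            r0 - pad < 0
            or c0 - pad < 0
            or r1 + pad > data.shape[0]
            or c1 + pad > data.shape[1]
        )
        rois.append(
            Roi(
                row_min=max(r0 - pad, 0),
                row_max=min(r1 + pad, data.shape[0]),
                col_min=max(c0 - pad, 0),
                col_max=min(c1 + pad, data.shape[1]),
                touches_border=touches,
            )
        )
    return rois


def _initial_guess(img: PhaseImage, roi: Roi) -> DropletFit:
    """Heuristic start: centroid/R from the above-threshold mask, dn from peak phase."""
    rs, cs = roi.slices()
    patch = img.data[rs, cs]
    px = img.pixel_size_um
    background = float(np.median(patch))
    thr = background + 0.5 * (float(patch.max()) - background)
    mask = patch > thr
    if not mask.any():
        mask = patch >= patch.max()
    rows, cols = np.nonzero(mask)
    yc = (rows.mean() + roi.row_min) * px
    xc = (cols.mean() + roi.col_min) * px
    r_px = max(np.sqrt(mask.sum() / np.pi), 1.5)
    radius = r_px * px
    lam_um = img.wavelength_nm * 1e-3
    # peak phase over background corresponds to a chord of ~2R (sessile sphere)
    dn0 = max((float(patch.max()) - background) * lam_um / (2 * np.pi * 2 * radius), 1e-5)
    return DropletFit(
        dn=dn0, radius_um=radius, xc_um=xc, yc_um=yc, zeq_um=radius,
        phi0=background, z_index=img.z_index,
    )


def fit_droplet(
    img: PhaseImage,
    roi: Roi,
    init: DropletFit | None = None,
    regularization: Callable[[float, float], float] | None = None,
) -> DropletFit:
    """Nonlinear least-squares fit of the spherical-cap model over one ROI.

    Six free parameters: dn, R, xc, yc, Zeq, phi0.  Returns the fitted
    parameters with an adjusted R^2; fits that fail to converge or pin a
    parameter at its bound are flagged with ``adj_r2 = NaN``.
    """
    if init is None:
        init = _initial_guess(img, roi)
    rs, cs = roi.slices()
    patch = img.data[rs, cs]
    px = img.pixel_size_um
    yy, xx = np.mgrid[rs, cs]
    xum = xx.astype(float) * px
    yum = yy.astype(float) * px
    obs = patch.ravel()

    roi_half_um = 0.5 * max(patch.shape) * px
    lo = np.array([0.0, 2 * px, xum.min(), yum.min(), 0.0, obs.min() - 1.0])
    hi = np.array(
        [0.1, roi_half_um, xum.max(), yum.max(), 4 * roi_half_um, obs.max() + 1.0]
    )
    def residuals(p):
        f = DropletFit(dn=p[0], radius_um=p[1], xc_um=p[2], yc_um=p[3],
                       zeq_um=p[4], phi0=p[5])
        return (
            phase_forward_model(xum, yum, f, img.wavelength_nm, regularization)
            - patch
        ).ravel()

    # the cost surface has a degenerate valley for Zeq >= R (untruncated
    # sphere); a short multi-start over the truncation height avoids it
    sol = None
    obs_scale = max(float(np.ptp(obs)), 1e-12)
    for zeq_frac in (init.zeq_um / init.radius_um, 0.4, 0.7, 1.0):
        p0 = np.clip(
            np.array([init.dn, init.radius_um, init.xc_um, init.yc_um,
                      zeq_frac * init.radius_um, init.phi0]),
            lo + 1e-12, hi - 1e-12,
        )
        try:
            cand = least_squares(residuals, p0, bounds=(lo, hi), ftol=1e-10,
                                 xtol=1e-12, gtol=1e-12)
        except Exception:
            continue
        if sol is None or cand.cost < sol.cost:
            sol = cand
        if sol.cost < (1e-8 * obs_scale) ** 2 * obs.size:
            break
    if sol is None:
        return replace(init, adj_r2=np.nan, flagged=True, z_index=img.z_index)

    p = sol.x
    n = obs.size
    n_par = 6
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - n_par - 1)

    at_bound = bool(np.any(np.isclose(p[1], [lo[1], hi[1]], rtol=1e-6)))
    flagged = (not sol.success) or at_bound
    return DropletFit(
        dn=float(p[0]), radius_um=float(p[1]), xc_um=float(p[2]),
        yc_um=float(p[3]), zeq_um=float(p[4]), phi0=float(p[5]),
        adj_r2=np.nan if not sol.success else float(adj_r2),
        z_index=img.z_index, flagged=flagged,
    )


def filter_fits(
    fits: Sequence[DropletFit], threshold: float = ADJ_R2_THRESHOLD
) -> list[DropletFit]:
    """Keep fits whose adjusted R^2 reaches ``threshold`` (NaN never passes)."""
    return [f for f in fits if np.isfinite(f.adj_r2) and f.adj_r2 >= threshold]


def track_z(
    fits_by_plane: Sequence[Sequence[DropletFit]], gate_um: float = 1.0
) -> list[DropletFit]:
    """Link fits of the same droplet across z and keep each track's best fit.

    Greedy nearest-centroid linking plane to plane within a gating radius
    ``gate_um``; an ambiguous link resolves to the nearest centroid.  The
    representative fit of each track is the one with the largest adjusted
    R^2.
    """
    tracks: list[list[DropletFit]] = []
    open_heads: list[tuple[float, float, int]] = []  # (xc, yc, track idx)
    for plane in fits_by_plane:
        new_heads: list[tuple[float, float, int]] = []
        unmatched = list(plane)
        # match each open track to its nearest candidate inside the gate
        for xc, yc, ti in open_heads:
            if not unmatched:
                break
            d = [np.hypot(f.xc_um - xc, f.yc_um - yc) for f in unmatched]
            j = int(np.argmin(d))
            if d[j] <= gate_um:
                f = unmatched.pop(j)
                tracks[ti].append(f)
                new_heads.append((f.xc_um, f.yc_um, ti))
            else:
                new_heads.append((xc, yc, ti))
        for f in unmatched:
            tracks.append([f])
            new_heads.append((f.xc_um, f.yc_um, len(tracks) - 1))
        open_heads = new_heads

    out = []
    for track in tracks:
        finite = [f for f in track if np.isfinite(f.adj_r2)]
        best = max(finite or track, key=lambda f: (np.nan_to_num(f.adj_r2, nan=-1)))
        out.append(best)
    return out


def summarize_dn(fits: Sequence[DropletFit]) -> tuple[float, float, int]:
    """Mean refractive-index difference, its standard error, and N."""
    if len(fits) < 2:
        raise ValueError("need at least 2 fits for a SEM")
    dn = np.array([f.dn for f in fits], dtype=float)
    return float(dn.mean()), float(dn.std(ddof=1) / np.sqrt(dn.size)), dn.size
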