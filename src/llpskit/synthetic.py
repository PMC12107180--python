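"""Seed-controlled generators for every input the analysis pipeline consumes.

The generators encode the physical picture the package is built to test:
PGL-3 and RNA form condensates above a saturation boundary; MEX-5
binds RNA through independent sites and thereby lowers the *free* RNA
concentration, shifting the apparent boundary; coexisting compositions
are connected by straight tie lines of slope ``k_tie`` in the
(RNA, PGL-3) plane.  Each generator records its ground-truth parameters
and seed so that recovery tests can compare pipeline estimates against
the truth.

Also provided is a minimal binary Flory-Huggins common-tangent
construction (:func:`binary_phase_split`), the only free-energy
computation in the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq, fsolve

from . import frap as _frap
from . import qpi as _qpi
from .composition import mass_to_molar, molar_to_mass
from .config import POLY_RU_MOLAR_MASS

__all__ = [
    "BinodalModel",
    "FreeEnergyBinary",
    "PhaseSplit",
    "GroundTruth",
    "free_rna",
    "gen_phase_diagram",
    "binary_phase_split",
    "gen_phase_image",
    "gen_frap_series",
    "gen_binding_curve",
    "gen_fluor_stack",
    "half_step_profile",
]

RECORD_COLUMNS = [
    "droplet_id", "pgl3_uM", "rna_ng_per_uL", "mex5_uM", "p_demix",
    "pgl3_dilute_uM",
]


@dataclass(frozen=True)
class GroundTruth:
    """Named map of generator parameters attached to a synthetic dataset."""

    params: dict[str, Any]
    seed: int

    def __getitem__(self, key: str) -> Any:
        return self.params[key]


@dataclass(frozen=True)
class BinodalModel:
    """Parametric phase boundary with RNA sequestration by MEX-5.

    The saturation concentration of PGL-3 decays hyperbolically with free
    RNA, ``c_sat(r) = c_inf + a / (r + r0)`` (r in ng/uL).  MEX-5
    carries ``n_sites_m`` independent RNA-binding sites of dissociation
    constant ``kd_m``; only unbound RNA counts toward the boundary.

    Parameters
    ----------
    c_inf : PGL-3 concentration floor at high RNA (uM)
    a : boundary amplitude (uM * ng/uL)
    r0 : RNA offset (ng/uL)
    w : logistic classification width around the boundary (uM)
    k_tie : tie-line slope in the (RNA, PGL-3) plane (uM per ng/uL)
    kd_m : MEX-5 site dissociation constant (nM)
    n_sites_m : RNA-binding sites per MEX-5 molecule
    """

    c_inf: float = 0.5
    a: float = 10.0
    r0: float = 5.0
    w: float = 0.1
    k_tie: float = 0.02
    kd_m: float = 520.0
    n_sites_m: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.w <= 0:
            raise ValueError("w must be positive")
        if self.k_tie < 0:
            raise ValueError("k_tie must be non-negative")
        if self.n_sites_m < 1:
            raise ValueError("n_sites_m must be at least 1")
        if self.a <= 0 or self.r0 <= 0:
            raise ValueError("a and r0 must be positive")

    def c_sat(self, r):
        """Saturation PGL-3 concentration (uM) at free RNA ``r`` (ng/uL)."""
        return self.c_inf + self.a / (np.asarray(r, dtype=float) + self.r0)

    def c_sat_slope(self, r):
        """d c_sat / d r (uM per ng/uL); strictly negative."""
        return -self.a / (np.asarray(r, dtype=float) + self.r0) ** 2

    def response_gradient(self, r) -> float:
        """Slope of dilute-phase vs total PGL-3 at free RNA ``r``.

        Along a tie line of slope ``k_tie`` the dilute-phase PGL-3
        responds to the total as ``R = c'/(c' - k_tie)`` with
        ``c' = c_sat_slope(r)``; R lies in (0, 1].
        """
        c = self.c_sat_slope(r)
        return float(c / (c - self.k_tie))

    def dilute_phase(self, r_free: float, p_tot: float) -> float:
        """PGL-3 coordinate of the tie-line/binodal intersection (uM).

        The tie line of slope ``k_tie`` through the total composition
        ``(r_free, p_tot)`` meets the binodal at the dilute-phase
        composition.  Only meaningful when ``p_tot >= c_sat(r_free)``.
        """
        k = self.k_tie
        if k == 0:
            return p_tot

        def g(r):
            return self.c_sat(r) - p_tot - k * (r - r_free)

        if g(r_free) >= 0:  # on or below the boundary: no dense phase
            return p_tot
        lo = -self.r0 + 1e-9 * self.r0
        r_star = brentq(g, lo, r_free, xtol=1e-12, rtol=1e-14)
        return float(p_tot + k * (r_star - r_free))


def free_rna(r_tot, mex5, kd_m: float, n_sites_m: int = 2):
    """Unbound RNA under 1:1 site-level mass action (all in nM).

    MEX-5 at ``mex5`` nM carries ``n_sites_m`` identical independent
    sites, a total site concentration ``S = n_sites_m * mex5``.  The free
    RNA is the physical root of

        r^2 + (S + kd - r_tot) r - kd * r_tot = 0.

    Accepts scalars or arrays; returns values in [0, r_tot].
    """
    r_tot = np.asarray(r_tot, dtype=float)
    mex5 = np.asarray(mex5, dtype=float)
    if np.any(r_tot < 0) or np.any(mex5 < 0) or kd_m < 0 or n_sites_m < 0:
        raise ValueError("all inputs must be non-negative")
    S = n_sites_m * mex5
    if kd_m == 0:
        out = np.maximum(r_tot - S, 0.0)
    else:
        b = S + kd_m - r_tot
        out = 0.5 * (-b + np.sqrt(b * b + 4.0 * kd_m * r_tot))
        out = np.clip(out, 0.0, r_tot)
    return float(out) if out.ndim == 0 else out


def _logistic(z):
    from scipy.special import expit

    return expit(np.asarray(z, dtype=float))


def gen_phase_diagram(
    model: BinodalModel,
    n_droplets: int,
    conc_ranges: dict[str, tuple[float, float]] | None = None,
    seed: int | None = None,
    molar_mass: float = POLY_RU_MOLAR_MASS,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a microfluidic phase-diagram dataset.

    Each water-in-oil droplet gets total concentrations sampled uniformly
    from ``conc_ranges`` (keys ``pgl3_uM``, ``rna_ng_per_uL``,
    ``mex5_uM``).  Free RNA follows from site-level mass action with
    MEX-5; the demixing probability is logistic in the signed distance of
    total PGL-3 to the boundary at that free RNA; droplets on the demixed
    side (p >= 0.5) report the tie-line dilute-phase PGL-3, the rest
    report their total.

    Returns the record table and a :class:`GroundTruth` carrying the
    model parameters, including the analytic response gradient at the
    midpoint RNA level.
    """
    if n_droplets < 1:
        raise ValueError("n_droplets must be at least 1")
    ranges = conc_ranges or {
        "pgl3_uM": (0.05, 2.5),
        "rna_ng_per_uL": (1.0, 150.0),
        "mex5_uM": (0.0, 0.0),
    }
    for key in ("pgl3_uM", "rna_ng_per_uL", "mex5_uM"):
        lo, hi = ranges[key]
        if hi < lo or lo < 0:
            raise ValueError(f"invalid range for {key}")
    if seed is None:
        seed = model.seed
    rng = np.random.default_rng(seed)

    p_tot = rng.uniform(*ranges["pgl3_uM"], size=n_droplets)
    rna = rng.uniform(*ranges["rna_ng_per_uL"], size=n_droplets)
    mex5 = rng.uniform(*ranges["mex5_uM"], size=n_droplets)

    r_tot_nM = mass_to_molar(rna, molar_mass)
    r_free_nM = free_rna(r_tot_nM, mex5 * 1e3, model.kd_m, model.n_sites_m)
    r_free = molar_to_mass(r_free_nM, molar_mass)

    csat = model.c_sat(r_free)
    p_demix = _logistic((p_tot - csat) / model.w)
    dilute = np.where(
        p_demix >= 0.5,
        [model.dilute_phase(rf, pt) for rf, pt in zip(r_free, p_tot)],
        p_tot,
    )

    df = pd.DataFrame(
        {
            "droplet_id": np.arange(n_droplets),
            "pgl3_uM": p_tot,
            "rna_ng_per_uL": rna,
            "mex5_uM": mex5,
            "p_demix": p_demix,
            "pgl3_dilute_uM": dilute,
        }
    )
    r_mid = 0.5 * (ranges["rna_ng_per_uL"][0] + ranges["rna_ng_per_uL"][1])
    truth = GroundTruth(
        params={
            "c_inf": model.c_inf, "a": model.a, "r0": model.r0,
            "w": model.w, "k_tie": model.k_tie, "kd_m": model.kd_m,
            "n_sites_m": model.n_sites_m, "molar_mass": molar_mass,
            "rna_mid": r_mid,
            "R_true_mid": model.response_gradient(r_mid),
            "csat_mid": float(model.c_sat(r_mid)),
        },
        seed=seed,
    )
    return df, truth


# ---------------------------------------------------------------------------
# Binary Flory-Huggins common tangent
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FreeEnergyBinary:
    """Two-component mixing free energy f(phi) per lattice site (kT units).

    ``f(phi) = (phi/n) ln phi + (1 - phi) ln(1 - phi) + chi phi (1 - phi)``
    with polymerization degree ``n_poly`` and interaction parameter
    ``chi``.  ``grid`` is the composition discretization used for the
    initial bracket of the common tangent.
    """

    chi: float
    n_poly: float = 1.0
    grid: np.ndarray = field(
        default_factory=lambda: np.linspace(1e-6, 1.0 - 1e-6, 4001)
    )

    def __post_init__(self) -> None:
        if self.chi < 0:
            raise ValueError("chi must be non-negative")
        if self.n_poly < 1:
            raise ValueError("n_poly must be at least 1")

    def f(self, phi):
        phi = np.asarray(phi, dtype=float)
        if np.any(phi <= 0) or np.any(phi >= 1):
            raise ValueError("phi must lie in (0, 1)")
        return (
            phi / self.n_poly * np.log(phi)
            + (1 - phi) * np.log(1 - phi)
            + self.chi * phi * (1 - phi)
        )

    def df(self, phi):
        phi = np.asarray(phi, dtype=float)
        return (
            (np.log(phi) + 1) / self.n_poly
            - np.log(1 - phi) - 1
            + self.chi * (1 - 2 * phi)
        )


@dataclass(frozen=True)
class PhaseSplit:
    """Common-tangent result: coexisting compositions and lever rule."""

    psi_dil: float
    psi_dense: float
    nu: float  # dense-phase volume fraction at the queried phi_tot
    demixed: bool  # whether phi_tot falls inside the coexistence region


def _lower_hull_gap(phi: np.ndarray, f: np.ndarray) -> tuple[float, float] | None:
    """Largest composition gap skipped by the lower convex hull, or None."""
    # Andrew monotone chain on (phi, f), lower hull only
    hull: list[int] = []
    for i in range(phi.size):
        while len(hull) >= 2:
            j, k = hull[-2], hull[-1]
            cross = (phi[k] - phi[j]) * (f[i] - f[j]) - (f[k] - f[j]) * (
                phi[i] - phi[j]
            )
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    gaps = [
        (phi[hull[m + 1]] - phi[hull[m]], hull[m], hull[m + 1])
        for m in range(len(hull) - 1)
    ]
    width, i, j = max(gaps)
    dphi = phi[1] - phi[0]
    if width <= 2.5 * dphi:  # no skipped region: f is convex
        return None
    return float(phi[i]), float(phi[j])


def binary_phase_split(
    model: FreeEnergyBinary, phi_tot: float | None = None
) -> PhaseSplit | None:
    """Common-tangent (Maxwell) construction for the binary free energy.

    Finds the coexisting compositions ``psi_dil < psi_dense`` sharing a
    common tangent of ``f`` and, if ``phi_tot`` is given, the dense-phase
    volume fraction from the lever rule,
    ``nu = (phi_tot - psi_dil) / (psi_dense - psi_dil)``.

    Returns ``None`` when ``f`` is convex (no demixing).
    """
    if phi_tot is not None and not (0 < phi_tot < 1):
        raise ValueError("phi_tot must lie in (0, 1)")
    phi = np.asarray(model.grid, dtype=float)
    bracket = _lower_hull_gap(phi, model.f(phi))
    if bracket is None:
        return None
    p1, p2 = bracket

    def equations(v):
        a, b = v
        a = min(max(a, 1e-12), 1 - 1e-12)
        b = min(max(b, 1e-12), 1 - 1e-12)
        mu_a, mu_b = model.df(a), model.df(b)
        # equal chemical potential and equal grand potential (tangent touches)
        return [mu_a - mu_b, (model.f(b) - model.f(a)) - mu_a * (b - a)]

    sol, info, ier, _ = fsolve(equations, [p1, p2], full_output=True,
                               xtol=1e-13)
    psi_dil, psi_dense = sorted(float(s) for s in sol)
    if ier != 1 or psi_dense - psi_dil < 1e-9:
        psi_dil, psi_dense = p1, p2  # fall back to the hull bracket

    if phi_tot is None:
        nu = np.nan
        demixed = True
    else:
        nu = (phi_tot - psi_dil) / (psi_dense - psi_dil)
        demixed = psi_dil < phi_tot < psi_dense
        nu = float(np.clip(nu, 0.0, 1.0))
    return PhaseSplit(psi_dil=psi_dil, psi_dense=psi_dense, nu=nu,
                      demixed=demixed)


# ---------------------------------------------------------------------------
# Image, FRAP, binding-curve and fluorescence-stack generators
# ---------------------------------------------------------------------------


def gen_phase_image(
    fits: Sequence[_qpi.DropletFit],
    wavelength_nm: float = 650.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int] = (128, 128),
    pixel_size_um: float = 0.1,
    phi0: float = 0.0,
    seed: int = 0,
) -> _qpi.PhaseImage:
    """Render a phase image of sessile spherical-cap droplets.

    Pixelwise sums the cap forward model for each droplet (the constant
    offset ``phi0`` is global), then adds zero-mean Gaussian noise of
    standard deviation ``noise_sd`` radians.  Droplet footprints must not
    overlap -- the fitter assumes isolated caps.
    """
    if wavelength_nm <= 0:
        raise ValueError("wavelength must be positive")
    for i, fa in enumerate(fits):
        for fb in list(fits)[i + 1:]:
            d = np.hypot(fa.xc_um - fb.xc_um, fa.yc_um - fb.yc_um)
            if d < fa.radius_um + fb.radius_um:
                raise ValueError("droplet footprints overlap")
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    xum = xx * pixel_size_um
    yum = yy * pixel_size_um
    lam_um = wavelength_nm * 1e-3
    img = np.full(shape, phi0, dtype=float)
    for f in fits:
        img += (2 * np.pi / lam_um) * f.dn * _qpi.cap_height(xum, yum, f)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sd, size=shape)
    return _qpi.PhaseImage(data=img, wavelength_nm=wavelength_nm,
                           pixel_size_um=pixel_size_um)


def half_step_profile(x: np.ndarray, lo: float = 0.3, hi: float = 1.0) -> np.ndarray:
    """Idealized post-bleach initial profile: left half bleached to ``lo``."""
    x = np.asarray(x, dtype=float)
    mid = 0.5 * (x[0] + x[-1])
    return np.where(x < mid, lo, hi).astype(float)


def _solve_neumann_fine(u0, D, x, t, substeps):
    """Crank-Nicolson with no-flux ends (closed droplet), for generation."""
    from scipy.linalg import solve_banded

    n = x.size
    dx = x[1] - x[0]
    u = u0.copy()
    out = np.empty((t.size, n))
    out[0] = u0
    for k in range(1, t.size):
        dt = (t[k] - t[k - 1]) / substeps
        r = D * dt / dx**2
        ab = np.zeros((3, n))
        ab[0, 1:] = -r / 2
        ab[1, :] = 1 + r
        ab[2, :-1] = -r / 2
        # mirror ghost nodes at both ends
        ab[0, 1] = -r
        ab[2, -2] = -r
        for _ in range(substeps):
            lap = np.empty(n)
            lap[1:-1] = u[2:] - 2 * u[1:-1] + u[:-2]
            lap[0] = 2 * (u[1] - u[0])
            lap[-1] = 2 * (u[-2] - u[-1])
            rhs = u + (r / 2) * lap
            u = solve_banded((1, 1), ab, rhs)
        out[k] = u
    return out


def gen_frap_series(
    D: float,
    L: float,
    t_grid: np.ndarray,
    boundary_traces: tuple[np.ndarray, np.ndarray] | None = None,
    init_profile: np.ndarray | Callable[[np.ndarray], np.ndarray] | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    n_x: int = 41,
    refine: int = 4,
) -> tuple[_frap.FrapSeries, GroundTruth]:
    """Simulate half-bleach recovery profiles with known diffusivity.

    Profiles are computed on a reference grid ``refine`` times finer than
    the returned analysis grid (both space and time substeps).  With
    ``boundary_traces=None`` the droplet is closed (no-flux ends) and the
    recorded edge values play the role of experimentally measured
    boundary conditions; explicit Dirichlet traces may be supplied
    instead.

    Parameters
    ----------
    D : diffusion coefficient (um^2/s)
    L : droplet chord length (um)
    t_grid : frame times (s)
    noise_sd : additive Gaussian noise, in intensity units
    """
    if D <= 0 or L <= 0:
        raise ValueError("D and L must be positive")
    t = np.asarray(t_grid, dtype=float)
    x = np.linspace(0.0, L, n_x)
    x_fine = np.linspace(0.0, L, (n_x - 1) * refine + 1)
    if init_profile is None:
        u0_fine = half_step_profile(x_fine)
    elif callable(init_profile):
        u0_fine = np.asarray(init_profile(x_fine), dtype=float)
    else:
        u0_fine = np.interp(x_fine, x, np.asarray(init_profile, dtype=float))

    if boundary_traces is None:
        fine = _solve_neumann_fine(u0_fine, D, x_fine, t, substeps=10 * refine)
    else:
        bl, br = (np.asarray(b, dtype=float) for b in boundary_traces)
        if bl.size < t.size or br.size < t.size:
            raise ValueError("boundary traces shorter than t_grid")
        fine = _frap.solve_diffusion_1d(u0_fine, bl, br, D, x_fine, t,
                                        substeps=10 * refine)
    profiles = fine[:, ::refine]
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        profiles = profiles + rng.normal(0.0, noise_sd, size=profiles.shape)
    series = _frap.FrapSeries(x=x, t=t, profiles=profiles, edges=(0.0, L))
    truth = GroundTruth(params={"D_true": D, "L": L, "noise_sd": noise_sd},
                        seed=seed)
    return series, truth


def gen_binding_curve(
    kd: float,
    y_free: float,
    y_bound: float,
    x_grid: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a saturating single-site binding curve.

    ``y(x) = y_free + (y_bound - y_free) * x / (kd + x)`` plus additive
    Gaussian noise.  Warns when ``x_grid`` does not bracket ``kd``
    (the fitted Kd is then poorly identifiable).
    """
    if kd <= 0:
        raise ValueError("kd must be positive")
    x = np.asarray(x_grid, dtype=float)
    if np.any(x <= 0):
        raise ValueError("x_grid must be positive")
    if not (x.min() < kd < x.max()):
        warnings.warn("x_grid does not span kd: Kd poorly identifiable",
                      stacklevel=2)
    y = y_free + (y_bound - y_free) * x / (kd + x)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    df = pd.DataFrame({"x": x, "y": y})
    truth = GroundTruth(
        params={"Kd_true": kd, "y_free": y_free, "y_bound": y_bound,
                "noise_sd": noise_sd},
        seed=seed,
    )
    return df, truth


def gen_fluor_stack(
    radii: Sequence[float],
    positions: Sequence[tuple[float, float]],
    enrichment: float = 3.0,
    bulk_level: float = 100.0,
    dark_count: float = 100.0,
    noise_sd: float = 0.0,
    shape: tuple[int, int, int] = (15, 128, 128),
    pixel_size_um: float = 0.2,
    z_step_um: float = 0.7,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Render a fluorescence z-stack of spherical condensates.

    Spheres of the given radii (um) sit at (x, y) positions (um) in the
    mid-plane of the imaged volume; voxels inside a sphere read
    ``enrichment * bulk_level``, the rest ``bulk_level``; a camera dark
    count and Gaussian noise are added on top.
    """
    if enrichment < 1:
        raise ValueError("enrichment must be >= 1")
    radii = np.asarray(radii, dtype=float)
    if np.any(radii <= 0):
        raise ValueError("radii must be positive")
    nz, ny, nx = shape
    fov_x = nx * pixel_size_um
    fov_y = ny * pixel_size_um
    for r, (px, py) in zip(radii, positions):
        if px - r < 0 or px + r > fov_x or py - r < 0 or py + r > fov_y:
            raise ValueError("droplet extends outside the field of view")
    zc = 0.5 * (nz - 1) * z_step_um
    z = np.arange(nz)[:, None, None] * z_step_um
    y = np.arange(ny)[None, :, None] * pixel_size_um
    x = np.arange(nx)[None, None, :] * pixel_size_um
    stack = np.full(shape, bulk_level, dtype=float)
    for r, (px, py) in zip(radii, positions):
        inside = (x - px) ** 2 + (y - py) ** 2 + (z - zc) ** 2 <= r**2
        stack[inside] = enrichment * bulk_level
    stack += dark_count
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        stack = stack + rng.normal(0.0, noise_sd, size=shape)
    truth = GroundTruth(
        params={
            "radii": radii.tolist(),
            "positions": [tuple(p) for p in positions],
            "enrichment": enrichment, "bulk_level": bulk_level,
            "dark_count": dark_count,
            "bulk_volume_um3": fov_x * fov_y * nz * z_step_um,
        },
        seed=seed,
    )
    return stack, truth
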