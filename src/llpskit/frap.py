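"""Half-bleach FRAP analysis by 1D diffusion fitting.

After bleaching one half of a droplet, fluorescence along the droplet's
maximum diameter recovers by diffusion.  The analysis extracts a 1D
intensity profile per frame from a stripe across the droplet, detects
the droplet edges from the intensity drop-off, then treats the first
post-bleach profile as the initial condition of the 1D diffusion
equation

    dc/dt = D d2c/dx2   on [x_left, x_right]

with Dirichlet boundary values taken from the measured profile
endpoints (linearly interpolated in time).  The diffusion coefficient D
is the single fitted parameter: a bounded scalar search on log D
minimizes the misfit between the solved profiles and the observed ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import interp1d
from scipy.linalg import solve_banded
from scipy.optimize import minimize_scalar

__all__ = [
    "FrapSeries",
    "DiffusionFit",
    "extract_profile",
    "detect_edges",
    "solve_diffusion_1d",
    "fit_D",
    "diffusivity_ratio",
]


@dataclass(frozen=True)
class FrapSeries:
    """Space-time intensity profiles across a half-bleached droplet.

    Attributes
    ----------
    x : positions (um) along the droplet chord, strictly increasing
    t : frame times (s), strictly increasing
    profiles : intensity array of shape (len(t), len(x)), background-subtracted
    edges : (x_left, x_right) of the droplet (um)
    dark_count : camera offset already subtracted from ``profiles``
    """

    x: np.ndarray
    t: np.ndarray
    profiles: np.ndarray
    edges: tuple[float, float]
    dark_count: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        t = np.asarray(self.t, dtype=float)
        prof = np.asarray(self.profiles, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "profiles", prof)
        if np.any(np.diff(x) <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError("x and t must be strictly increasing")
        if prof.shape != (t.size, x.size):
            raise ValueError("profiles must have shape (len(t), len(x))")
        if not np.all(np.isfinite(prof)):
            raise ValueError("profiles must be finite")
        xl, xr = self.edges
        if not (x[0] - 1e-9 <= xl < xr <= x[-1] + 1e-9):
            raise ValueError("edges must lie within the x range")


@dataclass(frozen=True)
class DiffusionFit:
    """Result of the one-parameter diffusion fit."""

    D: float  # um^2/s
    residual: float
    converged: bool


def extract_profile(
    stack: np.ndarray,
    row: int,
    stripe_width: int = 6,
    dark_count: float = 0.0,
    pixel_size_um: float = 1.0,
    frame_interval_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-frame 1D intensity profiles from a horizontal stripe.

    Averages a ``stripe_width``-pixel-wide horizontal stripe centred on
    ``row`` along its short dimension for every frame and subtracts the
    camera dark count.

    Returns ``(x_um, t_s, profiles)`` with ``profiles[i]`` the profile of
    frame ``i``.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (frames, rows, cols)")
    half = stripe_width // 2
    r0, r1 = row - half, row - half + stripe_width
    if r0 < 0 or r1 > stack.shape[1]:
        raise ValueError("stripe extends outside the image")
    profiles = stack[:, r0:r1, :].mean(axis=1) - dark_count
    x = np.arange(stack.shape[2]) * pixel_size_um
    t = np.arange(stack.shape[0]) * frame_interval_s
    return x, t, profiles


def detect_edges(x: np.ndarray, profile: np.ndarray) -> tuple[float, float]:
    """Droplet edges from the half-height crossings of the intensity drop-off.

    Background is estimated from the profile ends, the plateau from the
    interior maximum; each edge is the position where intensity crosses
    half of (plateau - background), located by linear interpolation.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(profile, dtype=float)
    n_bg = max(2, p.size // 10)
    background = 0.5 * (p[:n_bg].mean() + p[-n_bg:].mean())
    plateau = p.max()
    if plateau - background <= 0:
        raise ValueError("no droplet detected: no plateau above background")
    half = background + 0.5 * (plateau - background)
    above = p >= half
    if not above.any():
        raise ValueError("no droplet detected: profile never crosses half height")
    i0, i1 = np.nonzero(above)[0][[0, -1]]

    def _interp(ia: int, ib: int) -> float:
        if ia == ib or p[ib] == p[ia]:
            return float(x[ia])
        f = (half - p[ia]) / (p[ib] - p[ia])
        return float(x[ia] + f * (x[ib] - x[ia]))

    x_left = _interp(i0 - 1, i0) if i0 > 0 else float(x[0])
    x_right = _interp(i1 + 1, i1) if i1 < p.size - 1 else float(x[-1])
    return x_left, x_right


def solve_diffusion_1d(
    init_profile: np.ndarray,
    boundary_left: np.ndarray,
    boundary_right: np.ndarray,
    D: float,
    x_grid: np.ndarray,
    t_grid: np.ndarray,
    substeps: int = 10,
) -> np.ndarray:
    """Crank-Nicolson solution of dc/dt = D d2c/dx2 with Dirichlet boundaries.

    ``boundary_left``/``boundary_right`` give the edge values at every
    time in ``t_grid`` (linearly interpolated at substeps).  Returns the
    solution sampled at ``t_grid`` with shape (len(t_grid), len(x_grid));
    the first row is the initial profile.
    """
    x = np.asarray(x_grid, dtype=float)
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(x) <= 0) or np.any(np.diff(t) <= 0):
        raise ValueError("grids must be strictly increasing")
    bl = np.asarray(boundary_left, dtype=float)
    br = np.asarray(boundary_right, dtype=float)
    if bl.size < t.size or br.size < t.size:
        raise ValueError("boundary traces shorter than t_grid")
    u0 = np.asarray(init_profile, dtype=float)
    if u0.size != x.size:
        raise ValueError("init_profile must match x_grid")

    dx = x[1] - x[0]
    if not np.allclose(np.diff(x), dx):
        raise ValueError("x_grid must be uniform")

    n = x.size
    bl_f = interp1d(t, bl[: t.size])
    br_f = interp1d(t, br[: t.size])

    out = np.empty((t.size, n))
    out[0] = u0
    u = u0.copy()
    for k in range(1, t.size):
        dt = (t[k] - t[k - 1]) / substeps
        r = D * dt / dx**2
        # banded matrices for the interior nodes (Dirichlet ends)
        m = n - 2
        ab = np.zeros((3, m))
        ab[0, 1:] = -r / 2
        ab[1, :] = 1 + r
        ab[2, :-1] = -r / 2
        for s in range(substeps):
            ta = t[k - 1] + s * dt
            tb = ta + dt
            ua, ub_l, ub_r = u, float(bl_f(tb)), float(br_f(tb))
            # explicit half uses the old boundary values already present in ua;
            # the implicit half moves the new boundary values to the RHS
            rhs = ua[1:-1] + (r / 2) * (ua[2:] - 2 * ua[1:-1] + ua[:-2])
            rhs[0] += (r / 2) * ub_l
            rhs[-1] += (r / 2) * ub_r
            interior = solve_banded((1, 1), ab, rhs)
            u = np.empty(n)
            u[0], u[-1] = ub_l, ub_r
            u[1:-1] = interior
        out[k] = u
    return out


def fit_D(
    series: FrapSeries,
    D_bounds: tuple[float, float] = (1e-4, 10.0),
    substeps: int = 10,
) -> DiffusionFit:
    """Fit the diffusion coefficient to a half-bleach profile series.

    The first frame is the initial condition; frames 2..n are data.  The
    profile is restricted to the detected droplet interior and the misfit
    is minimized over log10(D) with a bounded scalar search.
    """
    if series.t.size < 3:
        raise ValueError("need at least 3 frames (1 initial + 2 data)")
    xl, xr = series.edges
    inside = (series.x >= xl) & (series.x <= xr)
    if inside.sum() < 5:
        raise ValueError("too few points inside the droplet")
    x_in = series.x[inside]
    prof = series.profiles[:, inside]
    u0 = prof[0]
    if np.ptp(u0) < 1e-3 * max(abs(u0).max(), 1e-30):
        raise ValueError("no gradient to fit: initial profile is flat")
    # resample to a uniform grid, one node per original point
    x_u = np.linspace(x_in[0], x_in[-1], x_in.size)
    prof_u = np.vstack([np.interp(x_u, x_in, p) for p in prof])
    bl, br = prof_u[:, 0], prof_u[:, -1]
    data = prof_u[1:]
    scale = float(np.ptp(prof_u))

    def cost(logD: float) -> float:
        sol = solve_diffusion_1d(prof_u[0], bl, br, 10.0**logD, x_u,
                                 series.t, substeps)
        return float(np.sum((sol[1:] - data) ** 2)) / scale**2

    res = minimize_scalar(
        cost, bounds=(np.log10(D_bounds[0]), np.log10(D_bounds[1])),
        method="bounded", options={"xatol": 1e-4},
    )
    return DiffusionFit(D=float(10.0**res.x), residual=float(res.fun),
                        converged=bool(res.success))


def diffusivity_ratio(D_early: float, D_late: float) -> float:
    """Ratio D_early / D_late; > 1 indicates slowing (aging) dynamics."""
    if D_early <= 0 or D_late <= 0:
        raise ValueError("diffusion coefficients must be positive")
    return D_early / D_late
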