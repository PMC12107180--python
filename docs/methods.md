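# Methods

This note records the models implemented in `llpskit`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical choices that affect results.

## Optical model of a sessile droplet (qpi)

A droplet settled on a coverslip is modeled as a sphere of radius `R`
(µm) whose centre sits at height `Z_eq ≥ 0`, truncated below by the
coverslip plane. The vertical chord through the sphere at in-plane
distance ρ from the centroid is

    H(ρ) = max(0, Z_eq + s) − max(0, Z_eq − s),   s = √(R² − ρ²),

zero outside the footprint. The measured phase shift is
`Δφ = (2π/λ) Δn H + φ₀` with λ the illumination wavelength (650 nm
default) and `φ₀` a constant offset. An additive regularization term
`A(Z_eq, R)` used by some instruments is not defined here; the fitter
exposes a hook for a user-supplied callable and otherwise absorbs any
constant into `φ₀`. On synthetic data the fit is exact without it.

Fitting is bounded nonlinear least squares over the six parameters
(Δn ∈ [0, 0.1], R from 2 px to half the ROI). The cost surface has a
degenerate valley for `Z_eq ≥ R`: an untruncated sphere is
indistinguishable from a hemisphere with doubled Δn up to the offset,
so geometries with `Z_eq ≥ R` are not identifiable and a short
multi-start over the truncation height (fractions 0.4, 0.7, 1.0 of the
initial radius) keeps the optimizer off that branch for genuine caps.
Quality control keeps fits with adjusted R² ≥ 0.98
(`adj R² = 1 − (1 − R²)(n − 1)/(n − p − 1)`, p = 6). Across a z-stack,
droplets are linked by greedy nearest-centroid matching within a
configurable gate (default 1 µm; plane spacing 0.2 µm) and each track
reports the plane with the best adjusted R².

## Composition inference (composition)

The linear optical model
`Δn = (dn/dc)_p (c_p^cond − c_p^dil) + (dn/dc)_r (c_r^cond − c_r^dil)`
uses increments 0.1869 ml/g (protein, computed from sequence
composition) and 0.1665 ml/g (RNA, measured for poly-rA). The protein
uncertainty is propagated from the RNA one by relative scaling,
`σ_p = σ_r (dn/dc)_p/(dn/dc)_r = 0.005164 ml/g` — note reports often
round this to 0.0051. With dilute-phase concentrations set to zero and
equal increments, `c_polymer^cond = Δn/(dn/dc)_p`. For both species
partitioned ρ-fold into the dense phase with equal increments the
simplification under-reports the condensed total by exactly `100/ρ` %
(1% at 100-fold, 0.017% at 6000-fold); the two default increments
differ by 10.91%.

Mass concentrations are g/ml internally and mg/ml at the interface. A
`paper_style` flag applies report rounding (mg/ml to 2 decimals,
percent to 1 decimal, nM to integer); raw doubles otherwise. The
poly-rU molar mass constant is 9.09×10⁵ g/mol, which reproduces the
conventional pairing 20 ng/µL ↔ 22 nM and 30 ↔ 33; the pairing
140 ng/µL ↔ 156 nM implies a slightly smaller mass (8.97×10⁵ g/mol),
an inconsistency the package documents rather than resolves
(140 ng/µL converts to 154 nM at the package constant).

## FRAP diffusion fitting (frap)

Profiles are stripe averages (default 6 px) minus the camera dark
count; droplet edges come from half-height crossings of the intensity
drop-off with linear interpolation. The diffusion equation is solved by
Crank–Nicolson on a uniform grid (one node per pixel), each frame
interval subdivided 10×, with Dirichlet boundary values linearly
interpolated in time between the measured per-frame edge intensities.
The fit minimizes the summed squared misfit of frames 2..n over
log₁₀ D with a bounded scalar search (D ∈ [10⁻⁴, 10] µm²/s); frame 1 is
the initial condition, so no bleach-depth nuisance parameter is needed.
An optional intensity scale/offset nuisance is deliberately not fitted;
the fit is scale invariant as implemented. Solver accuracy: grid
doubling changes smooth-fixture solutions by <0.06% RMS; a perfectly
sharp bleach front is the worst case (~0.5% at the default resolution),
which is why the generator renders profiles on a ≥4× finer reference
grid.

The generator's closed-droplet mode solves with no-flux ends and hands
the analysis the recorded edge traces, mimicking "experimentally
determined" boundary conditions; an explicit Dirichlet mode exists for
closed-form checks (sine-mode decay `exp(−Dπ²t/L²)` is reproduced to
0.2%).

## Fluorescence quantification (fluor)

Stacks are reduced to 2D maximum projections, dark-corrected, median
filtered (3×3 — the concrete filter is a documented default, not a
claim about any particular original macro), Gaussian smoothed (1 px),
Otsu thresholded and labelled (min area 5 px). Otsu always splits a
histogram, so fields whose foreground–background contrast is below 3×
the background noise are declared empty. Volumes use the z-projected
equivalent-circle radius assuming sphericity; the bulk volume is field
area × imaging depth (default 10.5 µm, i.e. a 10–11 µm z-range at
0.7 µm steps). Enrichment is mean(inside)/mean(outside) on the
dark-corrected projection. The Welch t-test utility labels significance
at the `*P<0.5, **P<0.01, ***P<0.001` thresholds used in the field's
reports (the first threshold is reproduced as printed there, loose as
it is; `significance_stars` also returns "ns" above it).

## Phase-diagram thermodynamics (thermo)

Records carry totals (PGL-3 µM, RNA ng/µL, MEX-5 µM), a demixing
probability, and the dilute-phase PGL-3 concentration. Read-outs:

- **c_sat dose–response**: per MEX-5 level, records with RNA within
  ±0.2 ng/µL (configurable) of the slice are fit with a monotone
  logistic in total PGL-3; c_sat is the 0.5 crossing. The error band is
  the SD of PGL-3 values of records with demixing probability in
  [0.46, 0.54]. The ±0.2 window is interpreted in ng/µL.
- **Bands**: dilute-phase PGL-3 is binned half-open at 0.25 µM spacing
  (value 0.25 → band 2); a 0–2 µM axis gives 8 bands.
- **Contour slope K**: for contour levels inside the 1.55–1.95 µM
  dilute-phase window, demixed records within ±0.05 µM of a level are
  regressed (total PGL-3 on RNA); K is the mean slope and the quoted SD
  is across levels within the window. Default levels are four points
  spread over the window rather than only the 0.25 µM band edges (the
  window contains a single such edge, which would leave the SD
  undefined). K lower-bounds the tie-line component ratio; with a
  competitor binding RNA it also shrinks because free RNA responds
  sublinearly to total RNA.
- **Dominance**: at a fixed-RNA slice, OLS (unweighted) of dilute-phase
  on total PGL-3 over demixed records gives the response gradient R;
  Dominance = 1 − R, valid when the condensate volume fraction is
  small. The slope's standard error is reported.

The stand-in droplet classifier scores within-droplet intensity
heterogeneity (coefficient of variation) through a logistic
(midpoint 0.15, width 0.03); it exists so image crops can be classified
without a trained network, and the pipeline equally accepts precomputed
probability columns. Dilute-phase concentration from images averages
the pixels between the 5th and 25th intensity percentiles inside the
droplet mask and converts via a linear intensity→concentration
calibration (≥2 standards; extrapolation beyond 1.5× their range
warns).

## Binding isotherms (binding)

Both assay forms fit `y = A + B·x/(K_d + x)` by least squares
(initialized at min(y), the range of y, and the geometric mean of x),
equivalent to `A + B/(1 + K_d/x)`; in semilog-x the inflection sits at
`x = K_d` (verified numerically in the tests). The sizing form is the
simplest one consistent with that inflection property; a log-x logistic
alternative was considered and not adopted. No ligand-depletion
correction is applied (free ≈ total, appropriate at ~1 µM protein).
Fits are flagged when the optimizer fails, when the fitted K_d falls
outside the sampled concentration range by more than 3×, or when the
modeled signal change across the sampled range is below 3× the residual
noise (e.g. a non-binding zinc-finger deletion control). Standard
errors come from the least-squares covariance.

## Synthetic-data generators (synthetic)

The generators define the study conditions for every recovery test.

- **Mechanism**: MEX-5 at m µM contributes `S = 2m` µM of independent
  identical RNA-binding sites with dissociation constant `kd_m`
  (default 520 nM, the measured sizing K_d); free RNA is the positive
  root of `r² + (S + k_d − r_tot) r − k_d r_tot = 0`. Cooperativity is
  not modeled — nothing in the data motivates it. PGL-3's six sites do
  not enter the boundary model explicitly; their effect is folded into
  the empirical binodal.
- **Binodal**: `c_sat(r) = c_inf + a/(r + r0)` in *free* RNA, defaults
  c_inf = 0.5 µM, a = 10 µM·ng/µL, r0 = 5 ng/µL — chosen so the
  boundary traverses the 0–2.5 µM PGL-3, 1–150 ng/µL RNA region the
  dilute-phase banding (8 × 0.25 µM) presumes. Demixing probability is
  logistic in the signed distance to the boundary with width
  w = 0.1 µM.
- **Tie lines**: straight with constant slope `k_tie` (default
  0.02 µM per ng/µL) in the (RNA, PGL-3) plane; the dilute phase of a
  demixed droplet is the PGL-3 coordinate of the tie line/binodal
  intersection. Consequences worth knowing: at a fixed-RNA slice the
  response gradient is `R = c'/(c' − k_tie)` evaluated where the tie
  line meets the binodal, so a curved binodal makes R vary along the
  slice; recovery tests that target a specific R use a gently curved
  configuration (large r0) where R is nearly constant. Sampling of
  per-droplet totals is uniform over the stated ranges — a stand-in for
  the unknown flow-rate-driven distribution on chip, not an inferred
  fact.
- **Free energy**: the binary Flory–Huggins density
  `f(φ) = (φ/n) ln φ + (1 − φ) ln(1 − φ) + χ φ(1 − φ)`; the common
  tangent is bracketed by the lower convex hull of f on a grid
  (4001 points default) and refined by solving equal chemical potential
  and equal grand potential (`fsolve`, xtol 10⁻¹³). Convex f returns
  "no demixing". This is deliberately minimal: no ternary coexistence
  solver is provided or intended.
- **Images/stacks**: spherical-cap phase images (additive Gaussian
  noise in radians; overlapping footprints rejected) and 3D-rendered
  fluorescent spheres over a uniform bulk with dark count and noise.
- All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical seed and configuration give
  bit-identical outputs. Every generator returns its ground truth
  alongside the data.

What the generators do **not** emulate: droplet hardening and aging
kinetics (aging enters only as a lowered D between two runs),
photobleaching during acquisition, optical aberrations and PSF blur,
tie-line curvature, polydisperse RNA length, the surface chemistry of
filter-binding assays, and realistic classifier failure modes beyond
logistic blur at the boundary. Passing recovery tests therefore show
the estimators are correct under their stated model assumptions, not
that those assumptions hold for any particular instrument.

## Problem sizes and tolerances

Recovery studies use 20 seeds for FRAP (13 frames, 41 spatial nodes,
4 µm chord, 1% noise) and 50 seeds for binding (12 points over
0.01–50 µM, 2% noise) and QPI (96×96 px, 0.01 rad noise); phase-diagram
analyses use 2 000–6 000 droplets per condition. These sizes keep each
study at seconds of runtime while leaving the medians far inside the
stated tolerances (FRAP within 10%, K_d within 15%, Δn within 1%,
contour slope within 15%, dominance within 0.05). Noiseless QPI round
trips demand relative error < 10⁻⁶; the phase-split solver agrees with
a 10⁵-point grid-search oracle to 10⁻⁴ in composition.
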