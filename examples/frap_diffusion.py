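"""Recover a diffusion coefficient from a half-bleach FRAP series.

Simulates recovery of a half-bleached 4 um droplet with a known
diffusivity, then fits the 1D diffusion equation with measured boundary
values to the noisy profiles.
"""

import numpy as np

from llpskit import frap, synthetic as syn

D_TRUE = 0.056  # um^2/s, typical for PGL-3 condensates
t_grid = np.linspace(0.0, 60.0, 13)

series, truth = syn.gen_frap_series(D=D_TRUE, L=4.0, t_grid=t_grid,
                                    noise_sd=0.01, seed=7)
fit = frap.fit_D(series)

print(f"ground-truth D : {truth['D_true']:.4f} um^2/s")
print(f"fitted D       : {fit.D:.4f} um^2/s "
      f"({100 * abs(fit.D - D_TRUE) / D_TRUE:.1f}% off)")
print(f"converged      : {fit.converged}")
print()
print("The first profile seeds the 1D diffusion equation; the per-frame")
print("edge intensities act as Dirichlet boundary data, and D is the only")
print("fitted parameter.  Values of 0.04-0.08 um^2/s are typical of")
print("liquid protein/RNA condensates.")
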