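"""Fit dissociation constants from the two binding-assay geometries.

Simulates a diffusional-sizing curve (hydrodynamic radius vs RNA) and a
filter-binding curve (bound signal vs protein), fits both isotherms, and
reports the affinity fold ratio.
"""

import numpy as np

from llpskit import binding, synthetic as syn

x = np.logspace(np.log10(0.01), np.log10(50.0), 12)  # uM, 2 decades+

# MEX-5 sizing curve: radius grows from 3 nm (free) to 10 nm (RNA-bound)
mex5_curve, _ = syn.gen_binding_curve(0.52, 3.0, 10.0, x,
                                      noise_sd=0.02 * 7.0, seed=1)
mex5_fit = binding.fit_sizing_curve(mex5_curve["x"], mex5_curve["y"])

# PGL-3 sizing curve with its weaker affinity
pgl3_curve, _ = syn.gen_binding_curve(3.42, 4.0, 12.0, x,
                                      noise_sd=0.02 * 8.0, seed=2)
pgl3_fit = binding.fit_sizing_curve(pgl3_curve["x"], pgl3_curve["y"])

fold = binding.kd_fold_ratio(pgl3_fit.kd, mex5_fit.kd, paper_style=True)

print(f"MEX-5 sizing Kd : {mex5_fit.kd:.3f} uM "
      f"(Rh {mex5_fit.baseline:.1f} -> {mex5_fit.plateau:.1f} nm)")
print(f"PGL-3 sizing Kd : {pgl3_fit.kd:.3f} uM")
print(f"affinity ratio  : {fold:.0f}-fold higher for MEX-5")

# a non-binding control (zinc-finger deletion) comes back flagged
flat, _ = syn.gen_binding_curve(0.52, 5.0, 5.0, x, noise_sd=0.05, seed=3)
control = binding.fit_sizing_curve(flat["x"], flat["y"])
print(f"dZF control flagged (no binding): {control.flagged}")
print()
print("The inflection of the radius curve in semilog-x sits at Kd; a")
print("several-fold lower Kd means MEX-5 outcompetes PGL-3 for RNA.")
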