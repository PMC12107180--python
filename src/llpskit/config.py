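"""Shared physical constants and defaults.

Values used across the composition, phase-diagram, and synthetic-data
modules live here so that every unit conversion in the package agrees.
"""

#: Average molar mass of the poly-rU stock (g/mol).  Commercial poly-rU is a
#: broad length distribution; this effective value makes the package's
#: mass <-> molar conversions reproduce the conventional pairing of
#: 20 ng/uL with 22 nM.  Printed pairs at the high-concentration end imply a
#: slightly smaller mass (8.97e5 g/mol for 140 ng/uL <-> 156 nM); see
#: docs/methods.md for the discrepancy.
POLY_RU_MOLAR_MASS = 9.09e5

#: Refractive-index increment of PGL-3 protein (ml/g), estimated from its
#: amino-acid composition.
DN_DC_PROTEIN = 0.1869
#: Uncertainty on the protein increment (ml/g).
DN_DC_PROTEIN_SIGMA = 0.0051

#: Refractive-index increment of homopolymeric RNA (ml/g), measured for
#: poly-rA and taken as representative for poly-rU.
DN_DC_RNA = 0.1665
#: Uncertainty on the RNA increment (ml/g).
DN_DC_RNA_SIGMA = 0.0046

#: QPI illumination wavelength (nm).
QPI_WAVELENGTH_NM = 650.0

#: z-spacing of QPI hologram stacks (um).
QPI_DZ_UM = 0.2

#: Adjusted-R^2 acceptance threshold for spherical-cap fits.
ADJ_R2_THRESHOLD = 0.98

#: Default imaging depth (um) used to compute the bulk volume of a
#: fluorescence field (10-11 um z range at 0.7 um step).
IMAGING_DEPTH_UM = 10.5
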