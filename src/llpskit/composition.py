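"""Condensate composition from refractive-index differences.

Quantitative phase imaging yields the refractive-index difference
``dn`` between a condensate and the surrounding dilute phase.  Under a
linear mixing model this difference is a weighted sum of the protein and
RNA concentration imbalances between the phases,

    dn = (dn/dc)_p (c_p^cond - c_p^dil) + (dn/dc)_r (c_r^cond - c_r^dil),

with the refractive-index increments (dn/dc) of each species as weights.
When the dilute-phase concentrations are negligible and the two
increments are nearly equal, the model collapses to a single-species
form and the total condensed polymer mass concentration is simply
``dn / (dn/dc)_p``.  This module implements both forms, the error budget
of the approximation, and the unit conversions used throughout the
package.

Mass concentrations are g/ml internally; the public interface speaks
mg/ml (and ng/uL for RNA), which are the units practitioners use.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import (
    DN_DC_PROTEIN,
    DN_DC_PROTEIN_SIGMA,
    DN_DC_RNA,
    DN_DC_RNA_SIGMA,
    POLY_RU_MOLAR_MASS,
)

__all__ = [
    "OpticalIncrements",
    "PhaseComposition",
    "dn_from_composition",
    "polymer_conc_from_dn",
    "approximation_error",
    "propagate_dndc_sigma",
    "increments_relative_difference",
    "percent_change",
    "mass_to_molar",
    "molar_to_mass",
]


@dataclass(frozen=True)
class OpticalIncrements:
    """Refractive-index increments of the two polymer species (ml/g)."""

    dn_dc_p: float = DN_DC_PROTEIN
    dn_dc_r: float = DN_DC_RNA
    sigma_p: float = DN_DC_PROTEIN_SIGMA
    sigma_r: float = DN_DC_RNA_SIGMA

    def __post_init__(self) -> None:
        if min(self.dn_dc_p, self.dn_dc_r, self.sigma_p, self.sigma_r) <= 0:
            raise ValueError("increments and uncertainties must be positive")


@dataclass(frozen=True)
class PhaseComposition:
    """Protein/RNA mass concentrations in the two coexisting phases (mg/ml)."""

    cp_cond: float
    cp_dil: float
    cr_cond: float
    cr_dil: float

    def __post_init__(self) -> None:
        for c in (self.cp_cond, self.cp_dil, self.cr_cond, self.cr_dil):
            if c < 0:
                raise ValueError("concentrations must be non-negative")

    @property
    def c_polymer_cond(self) -> float:
        """Total condensed polymer mass concentration (mg/ml)."""
        return self.cp_cond + self.cr_cond


def dn_from_composition(
    comp: PhaseComposition, inc: OpticalIncrements | None = None
) -> float:
    """Refractive-index difference implied by a two-phase composition.

    Parameters
    ----------
    comp
        Concentrations of protein and RNA in both phases, in mg/ml.
    inc
        Refractive-index increments; package defaults if omitted.
    """
    inc = inc or OpticalIncrements()
    # interface mg/ml -> internal g/ml
    dcp = (comp.cp_cond - comp.cp_dil) * 1e-3
    dcr = (comp.cr_cond - comp.cr_dil) * 1e-3
    return inc.dn_dc_p * dcp + inc.dn_dc_r * dcr


def polymer_conc_from_dn(
    dn: float, dn_dc_p: float = DN_DC_PROTEIN, *, paper_style: bool = False
) -> float:
    """Total condensed polymer concentration (mg/ml) from dn.

    Uses the single-increment approximation ``c = dn / (dn/dc)_p``, valid
    when dilute-phase concentrations are negligible and the protein and
    RNA increments are similar.

    Parameters
    ----------
    dn
        Measured refractive-index difference (dimensionless, >= 0).
    dn_dc_p
        Protein refractive-index increment (ml/g).
    paper_style
        Round to two decimals (report convention) instead of returning the
        raw double.
    """
    if dn_dc_p <= 0:
        raise ValueError("dn_dc_p must be positive")
    if dn < 0:
        raise ValueError("dn must be non-negative")
    c = dn / dn_dc_p * 1e3  # g/ml -> mg/ml
    return round(c, 2) if paper_style else c


def approximation_error(partition_ratio: float) -> float:
    """Relative error (%) of the single-increment concentration estimate.

    For a system in which both species are ``partition_ratio``-fold more
    concentrated in the dense phase and the two increments are equal, the
    exact two-species relation gives dn proportional to
    ``c_cond (1 - 1/ratio)`` while the simplified estimate divides dn by
    the increment directly; the estimate therefore deviates from the true
    condensed total by ``100/ratio`` percent.
    """
    if partition_ratio <= 1:
        raise ValueError("partition_ratio must exceed 1 (demixed system)")
    return 100.0 / partition_ratio


def propagate_dndc_sigma(
    sigma_r: float = DN_DC_RNA_SIGMA,
    dn_dc_p: float = DN_DC_PROTEIN,
    dn_dc_r: float = DN_DC_RNA,
) -> float:
    """Protein-increment uncertainty from the relative RNA uncertainty.

    The protein increment is computed, not measured, so its uncertainty is
    taken to have the same relative size as the measured RNA increment's:
    ``sigma_p = sigma_r * (dn/dc)_p / (dn/dc)_r``.
    """
    return sigma_r * dn_dc_p / dn_dc_r


def increments_relative_difference(inc: OpticalIncrements | None = None) -> float:
    """Relative difference (%) between the two increments, w.r.t. the protein's."""
    inc = inc or OpticalIncrements()
    return 100.0 * abs(inc.dn_dc_p - inc.dn_dc_r) / inc.dn_dc_p


def percent_change(c_before: float, c_after: float, *, paper_style: bool = False) -> float:
    """Relative change (%) from ``c_before`` to ``c_after``."""
    if c_before <= 0:
        raise ValueError("c_before must be positive")
    pct = 100.0 * (c_after - c_before) / c_before
    return round(pct, 1) if paper_style else pct


def mass_to_molar(
    c_mass: float | np.ndarray,
    molar_mass: float = POLY_RU_MOLAR_MASS,
    *,
    paper_style: bool = False,
):
    """Convert a mass concentration (ng/uL) to molar (nM).

    ng/uL equals mg/L; dividing by the molar mass in g/mol and scaling
    gives ``c_nM = c_mass * 1e6 / M``.  With ``paper_style`` the result is
    rounded to the nearest nM, the convention for axis labels.
    """
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    c = np.asarray(c_mass, dtype=float)
    if np.any(c < 0):
        raise ValueError("mass concentration must be non-negative")
    nM = c * 1e6 / molar_mass
    if paper_style:
        nM = np.round(nM)
    return float(nM) if np.isscalar(c_mass) else nM


def molar_to_mass(c_nM: float | np.ndarray, molar_mass: float = POLY_RU_MOLAR_MASS):
    """Convert a molar concentration (nM) back to mass units (ng/uL)."""
    if molar_mass <= 0:
        raise ValueError("molar_mass must be positive")
    c = np.asarray(c_nM, dtype=float)
    out = c * molar_mass / 1e6
    return float(out) if np.isscalar(c_nM) else out
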