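"""Quantification of condensates in fluorescence z-stacks.

Stacks are analyzed as 2D maximum projections: dark-count subtraction,
a median and light Gaussian filter, Otsu thresholding and labelling give
per-condensate masks and equivalent-circle radii.  Droplet volumes are
computed from the z-projected radii assuming sphericity; the volume
fraction divides the summed droplet volume by the imaged bulk volume
(field area times imaging depth).  Enrichment is the dark-corrected
mean intensity inside the condensate mask over the mean outside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage, stats
from skimage import measure
from skimage.filters import gaussian, threshold_otsu

from .config import IMAGING_DEPTH_UM

__all__ = [
    "CondensateSet",
    "segment_condensates",
    "volume_fraction",
    "enrichment",
    "normalized_volume",
    "welch_t_test",
    "significance_stars",
]


@dataclass(frozen=True)
class CondensateSet:
    """Segmentation result for one fluorescence field."""

    radii_um: np.ndarray  # z-projected equivalent-circle radii
    centroids_um: np.ndarray  # (n, 2) array of (x, y)
    mask: np.ndarray  # 2D boolean condensate mask
    mean_in: float  # dark-corrected mean intensity inside the mask
    mean_out: float  # dark-corrected mean intensity outside
    bulk_volume_um3: float

    @property
    def n(self) -> int:
        return int(self.radii_um.size)

    @property
    def total_volume_um3(self) -> float:
        return float(np.sum(4.0 / 3.0 * np.pi * self.radii_um**3))


def segment_condensates(
    stack: np.ndarray,
    dark_count: float = 0.0,
    pixel_size_um: float = 0.2,
    depth_um: float = IMAGING_DEPTH_UM,
    min_area_px: int = 5,
    saturation_level: float | None = None,
) -> CondensateSet:
    """Segment condensates on the maximum projection of a z-stack.

    Processing: max-project over z, subtract the camera dark count,
    median-filter (3x3) and Gaussian-smooth (1 px), Otsu-threshold,
    label, and drop objects below ``min_area_px``.  The bulk volume is
    the field area times ``depth_um``.
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim == 2:
        stack = stack[None]
    if saturation_level is not None and np.any(stack >= saturation_level):
        import warnings

        warnings.warn("saturated pixels present", stacklevel=2)
    proj = stack.max(axis=0) - dark_count
    smooth = gaussian(ndimage.median_filter(proj, size=3), sigma=1,
                      preserve_range=True)
    if np.ptp(smooth) == 0:
        mask = np.zeros_like(proj, dtype=bool)
    else:
        thr = threshold_otsu(smooth)
        mask = smooth > thr
        # Otsu always splits the histogram; reject splits that only carve
        # up noise (foreground barely brighter than background)
        if mask.any() and not mask.all():
            contrast = smooth[mask].mean() - smooth[~mask].mean()
            if contrast < 3.0 * smooth[~mask].std():
                mask = np.zeros_like(proj, dtype=bool)
    labels = measure.label(mask)
    radii, cents = [], []
    clean = np.zeros_like(mask)
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        radii.append(np.sqrt(region.area / np.pi) * pixel_size_um)
        cy, cx = region.centroid
        cents.append((cx * pixel_size_um, cy * pixel_size_um))
        clean[labels == region.label] = True

    inside = proj[clean]
    outside = proj[~clean]
    field_area = proj.size * pixel_size_um**2
    return CondensateSet(
        radii_um=np.asarray(radii, dtype=float),
        centroids_um=np.asarray(cents, dtype=float).reshape(-1, 2),
        mask=clean,
        mean_in=float(inside.mean()) if inside.size else np.nan,
        mean_out=float(outside.mean()) if outside.size else np.nan,
        bulk_volume_um3=field_area * depth_um,
    )


def volume_fraction(cs: CondensateSet) -> float:
    """Summed spherical droplet volume over the imaged bulk volume."""
    if cs.bulk_volume_um3 <= 0:
        raise ValueError("bulk volume must be positive")
    return cs.total_volume_um3 / cs.bulk_volume_um3


def enrichment(cs: CondensateSet) -> float:
    """Mean intensity inside condensates over the mean in the bulk.

    Both means are dark-corrected at segmentation time.  With no
    condensates segmented the field is homogeneous and the ratio is 1.
    """
    if cs.n == 0:
        return 1.0
    if not np.isfinite(cs.mean_out) or cs.mean_out <= 0:
        raise ValueError("bulk mean intensity must be positive")
    if cs.mask.all():
        raise ValueError("mask covers the whole field: no bulk reference")
    return cs.mean_in / cs.mean_out


def normalized_volume(
    series: Sequence[CondensateSet], t0_index: int = 0
) -> np.ndarray:
    """Per-frame total condensate volume relative to a reference frame."""
    volumes = np.array([cs.total_volume_um3 for cs in series], dtype=float)
    ref = volumes[t0_index]
    if ref <= 0:
        raise ValueError("reference frame has zero total volume")
    return volumes / ref


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Welch two-sample t statistic and two-sided p-value."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def significance_stars(p: float) -> str:
    """Report-convention significance label for a p-value."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.5:
        return "*"
    return "ns"
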