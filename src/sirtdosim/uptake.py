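"""SUV maps, fixed-threshold lesion segmentation and metabolic metrics.

Implements body-weight-normalized SUV, the 42%-of-maximum semi-automatic
lesion delineation, and the SUVmax / SUVmean / SUVpeak / TLG summary used
for metabolic response assessment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import ImageGrid

#: radius of the 1 mL SUVpeak sphere, mm
PEAK_SPHERE_RADIUS_MM = float((3.0 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0))

#: fixed segmentation threshold as a fraction of the in-mask maximum
THRESHOLD_FRACTION = 0.42


@dataclass
class SUVStats:
    """Metabolic summary of one lesion mask."""

    suv_max: float
    suv_mean: float
    suv_peak: float
    metabolic_volume_mL: float
    tlg: float  # g/mL * cm^3


def suv_map(conc: ImageGrid, injected_MBq: float,
            body_weight_kg: float) -> ImageGrid:
    """Convert an activity-concentration grid (kBq/mL) to SUVbw (g/mL).

    SUV = concentration / (injected activity / body weight); with kBq/mL,
    MBq and kg the unit factors cancel (1 MBq/kg == 1 kBq/g).
    """
    if injected_MBq <= 0:
        raise ValueError("injected activity must be positive")
    if body_weight_kg <= 0:
        raise ValueError("body weight must be positive")
    suv = conc.values / ((injected_MBq * 1e3) / (body_weight_kg * 1e3))
    return ImageGrid(suv, conc.spacing_mm, conc.origin_mm,
                     modality="suv", units="g/mL")


def segment_threshold42(suv: ImageGrid, search_mask: np.ndarray,
                        threshold_fraction: float = THRESHOLD_FRACTION) -> np.ndarray:
    """Segment a lesion at a fixed fraction of the maximum voxel value.

    Thresholds at ``threshold_fraction`` of the in-mask maximum, then keeps
    only the 26-connected component containing the hottest voxel.
    """
    search_mask = np.asarray(search_mask, bool)
    if not search_mask.any():
        raise ValueError("empty search mask")
    region = np.where(search_mask, suv.values, 0.0)
    peak = region.max()
    if peak <= 0:
        raise ValueError("no positive uptake inside the search region")
    above = region >= threshold_fraction * peak
    structure = np.ones((3, 3, 3), dtype=bool)  # 26-connectivity
    labeled, _ = ndimage.label(above, structure=structure)
    max_idx = np.unravel_index(np.argmax(region), region.shape)
    return labeled == labeled[max_idx]


def suv_peak(suv: ImageGrid, mask: np.ndarray,
             sphere_radius_mm: float = PEAK_SPHERE_RADIUS_MM) -> float:
    """Mean SUV over a sphere centered on the hottest in-mask voxel.

    The sphere is anatomic, not mask-restricted: voxels whose centers fall
    within the radius contribute even when they lie outside the mask.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    region = np.where(mask, suv.values, -np.inf)
    max_idx = np.unravel_index(np.argmax(region), region.shape)
    coords = [suv.axis_centers_mm(a) for a in range(3)]
    center = [coords[a][max_idx[a]] for a in range(3)]
    d2 = ((coords[0][:, None, None] - center[0]) ** 2
          + (coords[1][None, :, None] - center[1]) ** 2
          + (coords[2][None, None, :] - center[2]) ** 2)
    sphere = d2 <= sphere_radius_mm ** 2
    return float(suv.values[sphere].mean())


def suv_stats(suv: ImageGrid, mask: np.ndarray,
              sphere_radius_mm: float = PEAK_SPHERE_RADIUS_MM) -> SUVStats:
    """SUVmax/mean/peak, metabolic volume and TLG over a lesion mask."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    values = suv.values[mask]
    volume = float(np.count_nonzero(mask)) * suv.voxel_volume_mL
    mean = float(values.mean())
    return SUVStats(suv_max=float(values.max()), suv_mean=mean,
                    suv_peak=suv_peak(suv, mask, sphere_radius_mm),
                    metabolic_volume_mL=volume, tlg=mean * volume)
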