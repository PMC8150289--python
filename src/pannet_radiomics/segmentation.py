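"""Fixed-threshold SUV lesion segmentation and eligibility checks.

Segmentation keeps the voxels of a manually delineated ROI whose SUV is at
least a fixed fraction (default 40%) of the ROI's SUVmax, then retains the
26-connected component containing the SUVmax voxel. The >= inequality keeps
the operation idempotent and guarantees the hottest voxel always survives.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .imgio import LesionMask, SuvVolume

__all__ = ["suv_max", "threshold_segment", "check_eligibility"]


def suv_max(volume: SuvVolume, roi: LesionMask) -> float:
    """Maximum SUV over the ROI voxels (the single hottest voxel)."""
    roi.check_aligned(volume)
    return float(volume.values[roi.values].max())


def threshold_segment(
    volume: SuvVolume,
    manual_roi: LesionMask,
    fraction: float = 0.40,
) -> LesionMask:
    """Threshold a manual ROI at ``fraction`` x SUVmax and keep the hot component.

    Voxels inside ``manual_roi`` with SUV >= fraction * SUVmax(manual_roi)
    survive; of those, the 26-connected component containing the SUVmax voxel
    is returned. The result is never empty: the SUVmax voxel always passes.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    manual_roi.check_aligned(volume)
    vmax = suv_max(volume, manual_roi)
    keep = manual_roi.values & (volume.values >= fraction * vmax)

    inside = np.where(manual_roi.values & (volume.values == vmax))
    hot = tuple(int(axis[0]) for axis in inside)
    labels, _ = ndimage.label(keep, structure=np.ones((3, 3, 3), dtype=int))
    component = labels == labels[hot]
    return LesionMask(component, manual_roi.spacing, provenance="original")


def check_eligibility(mask: LesionMask, min_voxels: int = 64) -> tuple[bool, str]:
    """Whether a lesion is large enough for 64-level GLCM quantization.

    A mask with fewer voxels than grey levels cannot populate a 64-level
    co-occurrence matrix meaningfully; such lesions are excluded from feature
    extraction. Returns (eligible, reason).
    """
    n = mask.n_voxels
    if n < min_voxels:
        return False, f"lesion has {n} voxels, fewer than the {min_voxels} required"
    return True, f"lesion has {n} voxels (>= {min_voxels})"
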