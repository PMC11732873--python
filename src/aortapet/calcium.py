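"""Total aortic Agatston calcium scoring on low-dose CT.

The Agatston score quantifies macroscopic calcium burden: within the
(spill-over corrected) aortic mask, a 130 HU threshold is applied per
axial slice, connected pixel groups with area strictly greater than
1 mm^2 are lesions, and each lesion contributes area (mm^2) times a
density weight determined by its peak attenuation:

    130-199 HU -> 1,  200-299 -> 2,  300-399 -> 3,  >= 400 -> 4.

Lesions are 2D per-slice objects (the classic formulation defines them
by pixel area); a calcification spanning several slices yields one
record per slice. The classic score presumes 3 mm slices and no
thickness rescaling is applied here; a warning is logged when the input
slice spacing differs from 3 mm.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage import measure

from .imaging import AXIAL_AXIS, BinaryMask, ImageVolume, assert_same_geometry

__all__ = [
    "LesionRecord",
    "CalciumResult",
    "density_weight",
    "find_lesions",
    "agatston_total",
]

log = logging.getLogger(__name__)

DEFAULT_THRESHOLD_HU = 130.0
DEFAULT_MIN_AREA_MM2 = 1.0
EXPECTED_SLICE_MM = 3.0


@dataclass(frozen=True)
class LesionRecord:
    """One calcified lesion on one axial slice."""

    slice_index: int
    pixel_count: int
    area_mm2: float
    peak_hu: float
    weight: int
    score: float


@dataclass
class CalciumResult:
    lesions: list[LesionRecord]
    total_agatston: float

    @property
    def n_lesions(self) -> int:
        return len(self.lesions)


def density_weight(peak_hu: float) -> int:
    """Agatston density weight from a lesion's peak attenuation."""
    if peak_hu < DEFAULT_THRESHOLD_HU:
        raise ValueError(f"peak_hu must be >= 130 for a lesion, got {peak_hu}")
    if peak_hu < 200:
        return 1
    if peak_hu < 300:
        return 2
    if peak_hu < 400:
        return 3
    return 4


def find_lesions(
    ct: ImageVolume,
    mask: BinaryMask,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    connectivity: int = 8,
) -> list[LesionRecord]:
    """Per-slice connected supra-threshold components within the mask.

    Components with area strictly greater than ``min_area_mm2`` become
    lesion records, ordered by slice then by smallest flat pixel index.
    ``connectivity`` is 8 (diagonals connect, the calcium-scoring
    standard) or 4.
    """
    if ct.unit != "HU":
        raise ValueError(f"CT volume must be HU-valued, got unit {ct.unit!r}")
    assert_same_geometry(ct, mask)
    if mask.is_empty():
        raise ValueError("empty aortic mask")
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    skimage_conn = 2 if connectivity == 8 else 1
    dx, dy, dz = ct.spacing
    if abs(dz - EXPECTED_SLICE_MM) > 1e-6:
        log.warning(
            "slice spacing %.3f mm differs from the 3 mm the Agatston score "
            "presumes; no thickness rescaling is applied",
            dz,
        )
    pixel_area = dx * dy

    lesions: list[LesionRecord] = []
    for k in range(ct.shape[AXIAL_AXIS]):
        sl_mask = mask.data[:, :, k]
        if not sl_mask.any():
            continue
        sl_ct = ct.data[:, :, k]
        binary = sl_mask & (sl_ct >= threshold_hu)
        if not binary.any():
            continue
        labels, n = measure.label(
            binary, connectivity=skimage_conn, return_num=True
        )
        comps = []
        for lab in range(1, n + 1):
            pix = labels == lab
            npix = int(pix.sum())
            area = npix * pixel_area
            if area <= min_area_mm2:
                continue
            first_idx = int(np.flatnonzero(pix.ravel())[0])
            peak = float(sl_ct[pix].max())
            w = density_weight(peak)
            comps.append(
                (
                    first_idx,
                    LesionRecord(
                        slice_index=k,
                        pixel_count=npix,
                        area_mm2=area,
                        peak_hu=peak,
                        weight=w,
                        score=area * w,
                    ),
                )
            )
        comps.sort(key=lambda t: t[0])
        lesions.extend(rec for _, rec in comps)
    return lesions


def agatston_total(
    ct: ImageVolume,
    mask: BinaryMask,
    threshold_hu: float = DEFAULT_THRESHOLD_HU,
    min_area_mm2: float = DEFAULT_MIN_AREA_MM2,
    connectivity: int = 8,
) -> CalciumResult:
    """Total aortic Agatston score: sum of per-lesion area x weight."""
    lesions = find_lesions(ct, mask, threshold_hu, min_area_mm2, connectivity)
    total = float(sum(l.score for l in lesions))
    return CalciumResult(lesions=lesions, total_agatston=total)
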