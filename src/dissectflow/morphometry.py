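"""Lumen morphometry from segmentation stacks.

Volumes are slice-wise: labelled-pixel count x pixel area x slice
thickness.  Maximum diameters are per-axial-slice Feret (maximum
caliper) diameters of the labelled region, measured over the pixel
corner points so that a single pixel reports its diagonal.  Percent
changes between scans compose multiplicatively as ratios of volumes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist

__all__ = [
    "LumenMorphology",
    "lumen_volume",
    "percent_change",
    "compose_changes",
    "max_diameter",
    "measure_stack",
]


@dataclass
class LumenMorphology:
    """Per-scan volumetry and caliper summary."""

    tl_volume_mL: float
    fl_volume_mL: float
    tl_max_diameter_mm: float
    fl_max_diameter_mm: float


def lumen_volume(labels: np.ndarray, label: int, pixel_mm: float,
                 slice_thickness_mm: float) -> float:
    """Volume (mL) of one labelled lumen in a (nx, ny, nslices) stack."""
    if slice_thickness_mm <= 0 or pixel_mm <= 0:
        raise ValueError("pixel size and slice thickness must be > 0")
    count = int((np.asarray(labels) == label).sum())
    if count == 0:
        warnings.warn(f"label {label} absent from the stack; volume is 0",
                      stacklevel=2)
        return 0.0
    return count * pixel_mm**2 * slice_thickness_mm / 1000.0  # mm^3 -> mL


def percent_change(v_ref: float, v_new: float) -> float:
    """100 * (v_new - v_ref) / v_ref."""
    if v_ref <= 0:
        raise ValueError("reference volume must be > 0")
    return 100.0 * (v_new - v_ref) / v_ref


def compose_changes(changes) -> float:
    """Compose sequential percent changes multiplicatively.

    ``100 * (prod(1 + c_i/100) - 1)`` — the ratio-composition identity
    (V_b/V_a)(V_c/V_b) = V_c/V_a.  Order-independent.
    """
    c = np.asarray(changes, dtype=float)
    if np.any(c <= -100):
        raise ValueError("a percent change must exceed -100")
    return float(100.0 * (np.prod(1.0 + c / 100.0) - 1.0))


def _slice_feret(slice_mask: np.ndarray, pixel_mm: float) -> float:
    """Max caliper diameter of a 2-D region over pixel corner points."""
    ii, jj = np.nonzero(slice_mask)
    if ii.size == 0:
        return 0.0
    h = 0.5
    corners = np.concatenate([
        np.stack([ii - h, jj - h], axis=1),
        np.stack([ii - h, jj + h], axis=1),
        np.stack([ii + h, jj - h], axis=1),
        np.stack([ii + h, jj + h], axis=1),
    ]) * pixel_mm
    corners = np.unique(corners, axis=0)
    if corners.shape[0] > 3:
        try:
            hull = ConvexHull(corners)
            corners = corners[hull.vertices]
        except Exception:
            pass  # degenerate (collinear) regions: use all corners
    return float(pdist(corners).max())


def max_diameter(labels: np.ndarray, label: int, pixel_mm: float,
                 ) -> tuple[np.ndarray, float]:
    """Per-slice Feret diameters (mm) and the global maximum."""
    arr = np.asarray(labels) == label
    if not arr.any():
        raise ValueError(f"label {label} absent from the stack")
    per_slice = np.array([_slice_feret(arr[:, :, k], pixel_mm)
                          for k in range(arr.shape[2])])
    return per_slice, float(per_slice.max())


def measure_stack(labels: np.ndarray, pixel_mm: float,
                  slice_thickness_mm: float, tl_label: int = 1,
                  fl_label: int = 2) -> LumenMorphology:
    """Full morphometry of one scan's label stack."""
    def _diam(lab):
        try:
            return max_diameter(labels, lab, pixel_mm)[1]
        except ValueError:
            return 0.0

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tl_v = lumen_volume(labels, tl_label, pixel_mm, slice_thickness_mm)
        fl_v = lumen_volume(labels, fl_label, pixel_mm, slice_thickness_mm)
    return LumenMorphology(
        tl_volume_mL=tl_v, fl_volume_mL=fl_v,
        tl_max_diameter_mm=_diam(tl_label),
        fl_max_diameter_mm=_diam(fl_label),
    )
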