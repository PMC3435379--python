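"""Cross-sectional morphometry of scleral strips.

The cross-sectional area is measured from a segmentation of the OCT
image — a closed boundary polygon in physical millimetres, or a boolean
mask with pixel pitches — and the laterally-averaged thickness is the
area divided by the strip width.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from shapely.geometry import Polygon

__all__ = ["CrossSection", "cross_section_area", "mean_thickness"]


@dataclass
class CrossSection:
    """A segmented strip cross-section.

    Provide either ``boundary_mm`` (an (N, 2) closed simple polygon in mm)
    or ``mask`` plus ``pixel_pitch_mm = (dz, dx)``.  ``width_mm`` is the
    strip width used for the thickness (default 4 mm).
    """

    boundary_mm: Optional[np.ndarray] = None
    mask: Optional[np.ndarray] = None
    pixel_pitch_mm: Optional[Tuple[float, float]] = None
    width_mm: float = 4.0

    def __post_init__(self):
        if (self.boundary_mm is None) == (self.mask is None):
            raise ValueError("provide exactly one of boundary_mm or mask")
        if self.width_mm <= 0:
            raise ValueError("width must be positive")
        if self.mask is not None and self.pixel_pitch_mm is None:
            raise ValueError("mask input requires pixel_pitch_mm")


def cross_section_area(cs: CrossSection) -> float:
    """Cross-sectional area in mm^2 (shoelace for polygons, pixel count
    times pixel area for masks).  Self-intersecting polygons are an error."""
    if cs.boundary_mm is not None:
        poly = Polygon(np.asarray(cs.boundary_mm, dtype=float))
        if not poly.is_valid or not poly.is_simple:
            raise ValueError("boundary polygon is self-intersecting or degenerate")
        area = float(poly.area)
    else:
        dz, dx = cs.pixel_pitch_mm
        if dz <= 0 or dx <= 0:
            raise ValueError("pixel pitches must be positive")
        area = float(np.count_nonzero(cs.mask)) * dz * dx
    if area <= 0:
        raise ValueError("cross-section area must be positive")
    return area


def mean_thickness(area_mm2: float, width_mm: float) -> float:
    """Laterally-averaged thickness = area / width (mm)."""
    if area_mm2 <= 0 or width_mm <= 0:
        raise ValueError("area and width must be positive")
    return area_mm2 / width_mm
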