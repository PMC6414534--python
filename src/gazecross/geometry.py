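"""Screen geometry and pixel/visual-angle conversions.

Eye-movement thresholds (saccade velocity, smoothing kernels) are defined in
degrees of visual angle, while gaze samples arrive in screen pixels.  This
module holds the monitor description and the two conversions used throughout:

* :func:`pixels_to_degrees` — the exact angle subtended at the eye by a
  centred on-screen extent (chord formula), used for reporting extents such
  as the full monitor width.
* :meth:`ScreenGeometry.deg_per_px` — the local linear factor at the screen
  centre, used for per-sample displacements, which are tiny enough that the
  small-angle approximation is exact to well under 1%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class ScreenGeometry:
    """Monitor description: resolution, physical size and viewing distance.

    Parameters
    ----------
    width_px, height_px : int
        Screen resolution in pixels.
    width_mm, height_mm : float
        Physical display size in millimetres.
    distance_mm : float
        Viewing distance from the eye to the screen plane, millimetres.
    """

    width_px: int
    height_px: int
    width_mm: float
    height_mm: float
    distance_mm: float

    def __post_init__(self) -> None:
        for name in ("width_px", "height_px", "width_mm", "height_mm", "distance_mm"):
            v = getattr(self, name)
            if not math.isfinite(v) or v <= 0:
                raise ValueError(f"ScreenGeometry.{name} must be strictly positive, got {v!r}")

    @property
    def mm_per_px_x(self) -> float:
        return self.width_mm / self.width_px

    @property
    def mm_per_px_y(self) -> float:
        return self.height_mm / self.height_px

    def deg_per_px(self, axis: str) -> float:
        """Small-extent linear conversion factor at screen centre, deg/px."""
        mm = self.mm_per_px_x if axis == "x" else self.mm_per_px_y
        return math.degrees(mm / self.distance_mm)

    def degrees_to_pixels(self, degrees: float, axis: str = "x") -> float:
        """Linear (centre) conversion of a small angular extent to pixels."""
        return degrees / self.deg_per_px(axis)


#: Geometry of a 1920x1080 monitor, 521x293 mm, viewed at 600 mm --
#: subtends 46.9 deg horizontally and 27.4 deg vertically.
DEFAULT_GEOMETRY = ScreenGeometry(1920, 1080, 521.0, 293.0, 600.0)


def pixels_to_degrees(extent_px: float, axis: str, geometry: ScreenGeometry) -> float:
    """Visual angle in degrees subtended by a centred extent of ``extent_px``.

    Uses the exact chord formula ``2*atan(extent_mm / (2*distance_mm))``.

    Parameters
    ----------
    extent_px : float
        On-screen extent in pixels, >= 0.
    axis : {"x", "y"}
        Axis along which the extent lies (horizontal or vertical).
    geometry : ScreenGeometry

    Raises
    ------
    ValueError
        If ``extent_px`` is negative or ``axis`` is unknown.
    """
    if axis not in ("x", "y"):
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    if extent_px < 0:
        raise ValueError(f"extent_px must be non-negative, got {extent_px}")
    mm = extent_px * (geometry.mm_per_px_x if axis == "x" else geometry.mm_per_px_y)
    return math.degrees(2.0 * math.atan2(mm / 2.0, geometry.distance_mm))
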