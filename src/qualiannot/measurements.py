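"""Quantitative statistics over ROI pixels, mirroring Fiji's *run Measure*.

Rasterization conventions (ours, documented rather than pixel-identical to
ImageJ):

* RECTANGLE ``(left, top, w, h)`` covers pixels with ``x in [left, left+w)``
  and ``y in [top, top+h)``.
* OVAL includes every pixel whose center ``(x+0.5, y+0.5)`` lies inside the
  ellipse inscribed in the bounding box.
* POLYGON / FREEHAND use the even-odd (ray-crossing) rule evaluated at
  pixel centers.

Masks are clipped to the image; a ROI with no overlap raises
:class:`~qualiannot.errors.EmptyMaskError`. The standard deviation uses the
population convention (divide by N), matching ImageJ.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .errors import EmptyMaskError, ValidationError
from .roi_io import Roi, RoiKind


class Measurement(Enum):
    """Measurement names as in Fiji's Analyze > Set Measurements."""

    MEAN = "Mean"
    MIN = "Min"
    MAX = "Max"
    STDDEV = "StdDev"
    AREA = "Area"
    CENTROID_X = "X"
    CENTROID_Y = "Y"
    BBOX = "BBox"  # expands to BX, BY, Width, Height columns
    PERIMETER = "Perim"


#: default measurement set: mean/min/max grey level
DEFAULT_MEASUREMENTS = frozenset({Measurement.MEAN, Measurement.MIN, Measurement.MAX})

# canonical column ordering for tables
_COLUMN_ORDER: list[tuple[Measurement, tuple[str, ...]]] = [
    (Measurement.MEAN, ("Mean",)),
    (Measurement.MIN, ("Min",)),
    (Measurement.MAX, ("Max",)),
    (Measurement.STDDEV, ("StdDev",)),
    (Measurement.AREA, ("Area",)),
    (Measurement.CENTROID_X, ("X",)),
    (Measurement.CENTROID_Y, ("Y",)),
    (Measurement.BBOX, ("BX", "BY", "Width", "Height")),
    (Measurement.PERIMETER, ("Perim",)),
]


def measurement_columns(spec) -> list[str]:
    """Ordered table column names for a set of measurements."""
    spec = frozenset(spec)
    cols: list[str] = []
    for m, names in _COLUMN_ORDER:
        if m in spec:
            cols.extend(names)
    return cols


@dataclass(frozen=True)
class RoiMask:
    """Boolean raster of the pixels a ROI covers, clipped to the image.

    ``bounds`` is the (left, top, width, height) of the raster within the
    image; ``raster`` has shape ``(height, width)``. ``perimeter`` is the
    length of the ROI outline (from the geometry, not the raster).
    """

    bounds: tuple[int, int, int, int]
    raster: np.ndarray
    perimeter: float

    def __post_init__(self) -> None:
        left, top, width, height = self.bounds
        if self.raster.shape != (height, width):
            raise ValidationError(
                f"raster shape {self.raster.shape} != bounds extent {(height, width)}"
            )

    @property
    def area(self) -> int:
        return int(self.raster.sum())


def _polygon_even_odd(vertices, xs, ys) -> np.ndarray:
    """Vectorized even-odd point-in-polygon test at points (xs, ys)."""
    inside = np.zeros(xs.shape, dtype=bool)
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        crosses = (y1 > ys) != (y2 > ys)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (ys - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (xs < np.where(crosses, x_at, np.inf))
    return inside


def _roi_perimeter(roi: Roi) -> float:
    left, top, w, h = roi.bounds
    if roi.kind is RoiKind.RECTANGLE:
        return 2.0 * (w + h)
    if roi.kind is RoiKind.OVAL:
        # Ramanujan's second approximation for the ellipse circumference
        a, b = w / 2.0, h / 2.0
        if a + b == 0:
            return 0.0
        lam = (a - b) / (a + b)
        return math.pi * (a + b) * (1 + 3 * lam**2 / (10 + math.sqrt(4 - 3 * lam**2)))
    if roi.kind in (RoiKind.POLYGON, RoiKind.FREEHAND):
        pts = roi.vertices
        return float(
            sum(
                math.hypot(pts[(i + 1) % len(pts)][0] - x, pts[(i + 1) % len(pts)][1] - y)
                for i, (x, y) in enumerate(pts)
            )
        )
    if roi.kind is RoiKind.LINE:
        (x1, y1), (x2, y2) = roi.vertices
        return math.hypot(x2 - x1, y2 - y1)
    return 0.0


def rasterize(roi: Roi, image_shape: tuple[int, int]) -> RoiMask:
    """Turn a ROI into a boolean pixel mask within an image of ``(height, width)``."""
    img_h, img_w = image_shape
    left, top, w, h = roi.bounds
    if roi.kind is RoiKind.POINT:
        # each point marks the single pixel containing it
        w, h = w + 1, h + 1

    cl, ct = max(left, 0), max(top, 0)
    cr, cb = min(left + w, img_w), min(top + h, img_h)
    if cl >= cr or ct >= cb:
        raise EmptyMaskError(f"ROI {roi.name!r} does not overlap a {image_shape} image")

    cw, ch = cr - cl, cb - ct
    if roi.kind is RoiKind.RECTANGLE:
        raster = np.ones((ch, cw), dtype=bool)
    elif roi.kind is RoiKind.OVAL:
        cx, cy = left + w / 2.0, top + h / 2.0
        a, b = w / 2.0, h / 2.0
        yy, xx = np.mgrid[ct:cb, cl:cr]
        px, py = xx + 0.5, yy + 0.5
        raster = ((px - cx) / a) ** 2 + ((py - cy) / b) ** 2 < 1.0 if a > 0 and b > 0 else np.zeros((ch, cw), bool)
    elif roi.kind in (RoiKind.POLYGON, RoiKind.FREEHAND):
        yy, xx = np.mgrid[ct:cb, cl:cr]
        raster = _polygon_even_odd(roi.vertices, xx + 0.5, yy + 0.5)
    elif roi.kind is RoiKind.POINT:
        raster = np.zeros((ch, cw), dtype=bool)
        for x, y in roi.vertices:
            if cl <= x < cr and ct <= y < cb:
                raster[y - ct, x - cl] = True
    elif roi.kind is RoiKind.LINE:
        # 1-pixel-wide Bresenham trace
        raster = np.zeros((ch, cw), dtype=bool)
        (x1, y1), (x2, y2) = roi.vertices
        steps = max(abs(x2 - x1), abs(y2 - y1), 1)
        for t in range(steps + 1):
            x = round(x1 + (x2 - x1) * t / steps)
            y = round(y1 + (y2 - y1) * t / steps)
            if cl <= x < cr and ct <= y < cb:
                raster[y - ct, x - cl] = True
    else:  # pragma: no cover - enum is closed
        raise ValidationError(f"cannot rasterize kind {roi.kind}")

    if not raster.any():
        raise EmptyMaskError(f"ROI {roi.name!r} covers no pixel inside the image")
    return RoiMask((cl, ct, cw, ch), raster, _roi_perimeter(roi))


def full_mask(image_shape: tuple[int, int]) -> RoiMask:
    """Whole-image mask: used when an annotation applies to the entire image."""
    h, w = image_shape
    return RoiMask((0, 0, w, h), np.ones((h, w), dtype=bool), 2.0 * (w + h))


def measure(pixels: np.ndarray, mask: RoiMask | None = None, spec=DEFAULT_MEASUREMENTS) -> dict[str, float]:
    """Statistics over the masked pixels of a 2-D image.

    Returns a map keyed by table column name (``Mean``, ``Min``, ``Max``,
    ``StdDev``, ``Area``, ``X``, ``Y``, ``BX``, ``BY``, ``Width``,
    ``Height``, ``Perim``). With ``mask=None`` the whole image is measured.
    Area uses a calibration of 1 pixel²; the centroid is the mean of the
    included pixel centers.
    """
    pixels = np.asarray(pixels)
    if pixels.ndim != 2:
        raise ValidationError(f"measure expects a 2-D image, got shape {pixels.shape}")
    spec = frozenset(spec)
    if not spec:
        return {}
    if mask is None:
        mask = full_mask(pixels.shape)
    left, top, w, h = mask.bounds
    if left < 0 or top < 0 or left + w > pixels.shape[1] or top + h > pixels.shape[0]:
        raise ValidationError("mask bounds exceed the image")
    raster = mask.raster
    if not raster.any():
        raise EmptyMaskError("cannot measure an empty mask")
    values = pixels[top : top + h, left : left + w][raster]

    out: dict[str, float] = {}
    if Measurement.MEAN in spec:
        out["Mean"] = float(values.mean())
    if Measurement.MIN in spec:
        out["Min"] = float(values.min())
    if Measurement.MAX in spec:
        out["Max"] = float(values.max())
    if Measurement.STDDEV in spec:
        out["StdDev"] = float(values.std(ddof=0))
    if Measurement.AREA in spec:
        out["Area"] = float(raster.sum())
    if Measurement.CENTROID_X in spec or Measurement.CENTROID_Y in spec:
        yy, xx = np.nonzero(raster)
        if Measurement.CENTROID_X in spec:
            out["X"] = float((xx + left + 0.5).mean())
        if Measurement.CENTROID_Y in spec:
            out["Y"] = float((yy + top + 0.5).mean())
    if Measurement.BBOX in spec:
        out["BX"], out["BY"] = float(left), float(top)
        out["Width"], out["Height"] = float(w), float(h)
    if Measurement.PERIMETER in spec:
        out["Perim"] = float(mask.perimeter)
    # canonical column order
    order = measurement_columns(spec)
    return {k: out[k] for k in order if k in out}
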