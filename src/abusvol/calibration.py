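"""Pixel-to-physical calibration from an in-image scale reference.

ABUS viewers burn a scale annotation into exported slice images. Reading
that annotation — either a bar of known physical length or a filled square
of known physical area — yields the conversion factors needed to turn
pixel counts into cross-sectional areas:

* ``length_ratio``: centimetres per pixel edge,
* ``area_ratio``: square centimetres per pixel.

For a bar of ``L`` cm spanning ``n`` pixels, ``length_ratio = L / n`` and
``area_ratio = length_ratio**2``. For a square of known area ``A`` cm²
containing ``n`` pixels, ``area_ratio = A / n`` and
``length_ratio = sqrt(area_ratio)``. Both routes are exposed because a
scale annotation may be read either way; on the same image they agree.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import CalibrationError

__all__ = [
    "ScaleReference",
    "CalibrationResult",
    "pixel_area_ratio_from_square",
    "pixel_area_ratio_from_bar",
    "detect_scale_bar",
]


@dataclass(frozen=True)
class ScaleReference:
    """An in-image scale annotation.

    Parameters
    ----------
    kind
        ``"bar"`` (physical_extent in cm) or ``"square"`` (cm²).
    pixel_extent
        Pixels along the bar, or pixel count inside the square.
        Sub-pixel (non-integer) extents are allowed for bars.
    physical_extent
        Physical length (cm) or area (cm²) of the reference.
    """

    kind: str
    pixel_extent: float
    physical_extent: float

    def __post_init__(self) -> None:
        if self.kind not in ("bar", "square"):
            raise CalibrationError(f"unknown scale reference kind {self.kind!r}")
        if not (self.pixel_extent > 0 and math.isfinite(self.pixel_extent)):
            raise CalibrationError("pixel_extent must be positive and finite")
        if not (self.physical_extent > 0 and math.isfinite(self.physical_extent)):
            raise CalibrationError("physical_extent must be positive and finite")

    def calibrate(self) -> "CalibrationResult":
        if self.kind == "bar":
            return pixel_area_ratio_from_bar(self.pixel_extent, self.physical_extent)
        return pixel_area_ratio_from_square(self.pixel_extent, self.physical_extent)


@dataclass(frozen=True)
class CalibrationResult:
    """Conversion factors from pixels to physical units.

    ``length_ratio`` is in cm/pixel, ``area_ratio`` in cm²/pixel.
    """

    length_ratio: float
    area_ratio: float

    def __post_init__(self) -> None:
        if not (self.length_ratio > 0 and self.area_ratio > 0):
            raise CalibrationError("calibration ratios must be strictly positive")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {
                "length_ratio_cm_per_px": self.length_ratio,
                "area_ratio_cm2_per_px": self.area_ratio,
            },
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source: str | Path) -> "CalibrationResult":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        obj = json.loads(text)
        return cls(
            length_ratio=float(obj["length_ratio_cm_per_px"]),
            area_ratio=float(obj["area_ratio_cm2_per_px"]),
        )


def pixel_area_ratio_from_square(pixel_count: int, known_area: float) -> CalibrationResult:
    """Calibrate from a filled reference square of known physical area.

    Parameters
    ----------
    pixel_count
        Number of pixels counted inside the square (≥ 1).
    known_area
        Physical area of the square in cm².
    """
    if pixel_count < 1:
        raise CalibrationError("pixel_count must be at least 1")
    if not known_area > 0:
        raise CalibrationError("known_area must be positive")
    area_ratio = known_area / pixel_count
    return CalibrationResult(length_ratio=math.sqrt(area_ratio), area_ratio=area_ratio)


def pixel_area_ratio_from_bar(bar_pixel_length: float, bar_physical_length: float) -> CalibrationResult:
    """Calibrate from a scale bar of known physical length.

    Sub-pixel bar lengths are accepted so that endpoint coordinates need
    not be quantized to the pixel grid.
    """
    if not bar_pixel_length > 0:
        raise CalibrationError("bar_pixel_length must be positive")
    if not bar_physical_length > 0:
        raise CalibrationError("bar_physical_length must be positive")
    length_ratio = bar_physical_length / bar_pixel_length
    return CalibrationResult(length_ratio=length_ratio, area_ratio=length_ratio**2)


def detect_scale_bar(image: np.ndarray, row: int | None = None) -> float:
    """Measure the pixel length of a horizontal scale bar in a rendered image.

    Intended for images produced by :func:`abusvol.phantom.render_slice_image`,
    where the bar sits on a known row near the bottom edge. Real clinical
    images are calibrated by supplying the bar extent explicitly.

    Parameters
    ----------
    image
        2-D grayscale array; the bar is the longest run of foreground
        (> 0) pixels on ``row``.
    row
        Row index to scan. Defaults to the brightest row in the bottom
        10% of the image.

    Returns
    -------
    float
        Length of the bar in pixels.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise CalibrationError("expected a 2-D grayscale image")
    if row is None:
        start = max(int(img.shape[0] * 0.9), 0)
        band = img[start:]
        if band.size == 0 or not band.any():
            raise CalibrationError("no scale bar found in bottom band")
        row = start + int(np.argmax(band.sum(axis=1)))
    line = img[row] > 0
    if not line.any():
        raise CalibrationError(f"no foreground pixels on row {row}")
    # longest run of consecutive foreground pixels
    padded = np.concatenate(([0], line.view(np.int8), [0]))
    edges = np.flatnonzero(np.diff(padded))
    runs = edges[1::2] - edges[0::2]
    return float(runs.max())
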