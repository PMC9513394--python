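"""Planimetry: from a hand-drawn tumor outline to a pixel count and area.

The pixel method measures a cross-section by counting the pixels enclosed
by the manually drawn outline and multiplying by the calibrated
cm²-per-pixel ratio. Because an image editor's region selection is not
bit-for-bit reproducible, this module fixes a deterministic rasterization
rule:

* a pixel ``(i, j)`` is set iff its center ``(i + 0.5, j + 0.5)`` lies
  inside the polygon under the even-odd (ray-crossing parity) rule;
* centers that fall exactly on the boundary are resolved by a half-open
  convention — left and top edges inclusive, right and bottom exclusive —
  so that abutting regions tile the plane without double counting.

Self-intersecting (hand-drawn outlines can self-touch) contours are
rasterized under the same even-odd semantics with a warning.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import CalibrationResult
from .errors import ContourError

__all__ = [
    "Contour",
    "RegionMask",
    "rasterize_contour",
    "cross_section_area",
    "shoelace_area",
]


@dataclass(frozen=True)
class Contour:
    """A closed polygonal outline in pixel coordinates.

    Vertices are ``(x, y)`` pairs; sub-pixel coordinates are allowed.
    The polygon is implicitly closed (last vertex connects to the first).
    """

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ContourError("a contour needs at least 3 (x, y) vertices")
        if not np.isfinite(v).all():
            raise ContourError("contour vertices must be finite")
        object.__setattr__(self, "vertices", v)

    def __len__(self) -> int:
        return self.vertices.shape[0]

    def is_simple(self) -> bool:
        """True if the outline does not self-intersect."""
        from shapely.geometry import LineString

        ring = np.vstack([self.vertices, self.vertices[:1]])
        return LineString(ring).is_simple

    def mirrored(self, width: float) -> "Contour":
        """Reflect across the vertical line x = width / 2."""
        v = self.vertices.copy()
        v[:, 0] = width - v[:, 0]
        return Contour(v)

    # -- serialization ----------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x", "y"])
            w.writerows(self.vertices.tolist())

    @classmethod
    def from_csv(cls, path: str | Path) -> "Contour":
        with open(path, newline="") as fh:
            rows = list(csv.reader(fh))
        if rows and not _is_number_pair(rows[0]):
            rows = rows[1:]  # header
        return cls(np.array([[float(x), float(y)] for x, y in rows]))

    def to_geojson(self, path: str | Path | None = None) -> str:
        ring = np.vstack([self.vertices, self.vertices[:1]])
        payload = json.dumps({"type": "Polygon", "coordinates": [ring.tolist()]})
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_geojson(cls, source: str | Path) -> "Contour":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        obj = json.loads(text)
        if obj.get("type") != "Polygon":
            raise ContourError("expected a GeoJSON Polygon")
        ring = np.asarray(obj["coordinates"][0], dtype=float)
        if ring.shape[0] > 3 and np.allclose(ring[0], ring[-1]):
            ring = ring[:-1]
        return cls(ring)


def _is_number_pair(row: list[str]) -> bool:
    try:
        float(row[0]), float(row[1])
        return True
    except (ValueError, IndexError):
        return False


@dataclass
class RegionMask:
    """A binary raster of one tumor cross-section."""

    bitmap: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        b = np.asarray(self.bitmap)
        if b.ndim != 2:
            raise ContourError("mask bitmap must be 2-D")
        self.bitmap = b.astype(bool)

    @property
    def height(self) -> int:
        return self.bitmap.shape[0]

    @property
    def width(self) -> int:
        return self.bitmap.shape[1]

    @property
    def pixel_count(self) -> int:
        return int(self.bitmap.sum())

    def to_png(self, path: str | Path) -> None:
        from PIL import Image

        Image.fromarray(self.bitmap.astype(np.uint8) * 255, mode="L").save(path)

    @classmethod
    def from_png(cls, path: str | Path) -> "RegionMask":
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("L"))
        return cls(arr > 127)


def rasterize_contour(contour: Contour, width: int, height: int) -> RegionMask:
    """Rasterize a closed contour onto a ``height × width`` grid.

    A pixel is set iff its center lies inside the polygon under the
    even-odd rule; boundary-coincident centers follow the left/top
    inclusive half-open convention. Pixels whose centers fall outside the
    raster are clipped.

    Parameters
    ----------
    contour
        The outline, in pixel coordinates (x right, y down).
    width, height
        Raster dimensions in pixels.
    """
    if width < 1 or height < 1:
        raise ContourError("raster dimensions must be positive")
    if not contour.is_simple():
        warnings.warn(
            "contour self-intersects; rasterizing with even-odd fill",
            stacklevel=2,
        )
    v = contour.vertices
    bb_min = v.min(axis=0)
    bb_max = v.max(axis=0)
    if bb_min[0] < 0 or bb_min[1] < 0 or bb_max[0] > width or bb_max[1] > height:
        warnings.warn("contour extends beyond the raster; clipping", stacklevel=2)

    # restrict work to the bounding box
    i0 = max(int(np.floor(bb_min[0] - 0.5)), 0)
    j0 = max(int(np.floor(bb_min[1] - 0.5)), 0)
    i1 = min(int(np.ceil(bb_max[0] + 0.5)), width)
    j1 = min(int(np.ceil(bb_max[1] + 0.5)), height)
    bitmap = np.zeros((height, width), dtype=bool)
    if i1 <= i0 or j1 <= j0:
        return RegionMask(bitmap)

    px = np.arange(i0, i1) + 0.5            # (W,)
    py = np.arange(j0, j1) + 0.5            # (H,)
    x1, y1 = v[:, 0], v[:, 1]
    x2, y2 = np.roll(x1, -1), np.roll(y1, -1)

    crossings = np.zeros((j1 - j0, i1 - i0), dtype=np.int64)
    for k in range(len(v)):
        a1, b1, a2, b2 = x1[k], y1[k], x2[k], y2[k]
        if b1 == b2:
            continue  # horizontal edge never crosses a rightward ray
        straddles = (b1 > py) != (b2 > py)  # (H,)
        if not straddles.any():
            continue
        xint = a1 + (py - b1) * (a2 - a1) / (b2 - b1)  # (H,)
        crossings += (straddles[:, None]) & (px[None, :] < xint[:, None])
    bitmap[j0:j1, i0:i1] = (crossings % 2).astype(bool)
    return RegionMask(bitmap)


def cross_section_area(pixel_count: int, calibration: CalibrationResult) -> float:
    """Physical cross-sectional area: pixel count × cm²-per-pixel ratio."""
    if pixel_count < 0:
        raise ContourError("pixel_count cannot be negative")
    return pixel_count * calibration.area_ratio


def shoelace_area(contour: Contour) -> float:
    """Analytic polygon area in px² (diagnostic cross-check, not the
    measurement path — the pixel method counts pixels)."""
    v = contour.vertices
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
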