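"""Tumor volume by Cavalieri slice summation and by the caliper formula.

The pixel method sections the tumor on the coronal plane at fixed
intervals (0.1 cm on ABUS), measures each cross-section's area by
planimetry, and sums area × thickness over the slices — the Cavalieri
principle with no end correction. The traditional comparator is the
ellipsoid-style caliper volume L × W × H / 2, where L is the largest
coronal diameter, W the largest diameter perpendicular to it, and H the
anteroposterior extent.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import CalibrationResult
from .errors import EmptyTumorError, MeasurementError, SeriesError
from .planimetry import RegionMask

__all__ = [
    "SliceSeries",
    "CaliperMeasurement",
    "cavalieri_volume",
    "traditional_volume",
    "measure_calipers",
]

#: coronal inter-slice spacing used on the ABUS system, in cm
DEFAULT_SLICE_THICKNESS = 0.1


@dataclass(frozen=True)
class SliceSeries:
    """Ordered per-slice cross-sectional areas at fixed spacing.

    Parameters
    ----------
    areas
        One area (cm²) per coronal slice, in anatomical order.
    thickness
        Inter-slice spacing in cm (default 0.1).
    """

    areas: np.ndarray
    thickness: float = DEFAULT_SLICE_THICKNESS

    def __post_init__(self) -> None:
        a = np.asarray(self.areas, dtype=float).ravel()
        if a.size and ((a < 0).any() or not np.isfinite(a).all()):
            raise SeriesError("slice areas must be finite and non-negative")
        if not self.thickness > 0:
            raise SeriesError("slice thickness must be positive")
        object.__setattr__(self, "areas", a)

    def __len__(self) -> int:
        return self.areas.size

    def to_csv(self, path: str | Path) -> None:
        """Write (slice_index, area_cm2) rows plus a JSON sidecar with the
        thickness (``<path>.meta.json``)."""
        import json

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["slice_index", "area_cm2"])
            for i, a in enumerate(self.areas):
                w.writerow([i, a])
        Path(str(path) + ".meta.json").write_text(
            json.dumps({"thickness_cm": self.thickness}) + "\n"
        )

    @classmethod
    def from_csv(cls, path: str | Path, thickness: float | None = None) -> "SliceSeries":
        import json

        with open(path, newline="") as fh:
            rows = list(csv.DictReader(fh))
        rows.sort(key=lambda r: int(r["slice_index"]))
        areas = [float(r["area_cm2"]) for r in rows]
        if thickness is None:
            sidecar = Path(str(path) + ".meta.json")
            thickness = (
                json.loads(sidecar.read_text())["thickness_cm"]
                if sidecar.exists()
                else DEFAULT_SLICE_THICKNESS
            )
        return cls(np.array(areas), thickness)


@dataclass(frozen=True)
class CaliperMeasurement:
    """Caliper dimensions in cm: length ≥ width in the coronal plane,
    height anteroposterior."""

    length: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise MeasurementError("caliper dimensions must be positive")
        if self.length < self.width:
            raise MeasurementError("length must be the largest coronal diameter (length ≥ width)")


def cavalieri_volume(series: SliceSeries) -> float:
    """Sum of slice volumes: Σᵢ areaᵢ × thickness (cm³).

    An empty series has zero volume. There is no partial-slice end
    correction; the layer model treats each slice as a prism of the
    measured area.
    """
    return float(series.areas.sum() * series.thickness)


def traditional_volume(m: CaliperMeasurement) -> float:
    """Ellipsoid-style caliper volume: length × width × height / 2 (cm³)."""
    return m.length * m.width * m.height / 2.0


def _corner_points(mask: RegionMask) -> np.ndarray:
    """Corner lattice points of the occupied pixel footprints, (x, y)."""
    ys, xs = np.nonzero(mask.bitmap)
    if xs.size == 0:
        return np.empty((0, 2))
    corners = {
        (x + dx, y + dy)
        for x, y in zip(xs.tolist(), ys.tolist())
        for dx in (0, 1)
        for dy in (0, 1)
    }
    return np.array(sorted(corners), dtype=float)


def _max_chord(points: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest pairwise distance among points and its unit direction.

    Uses the convex hull to prune (the diameter is attained on hull
    vertices), then brute force over the hull.
    """
    if points.shape[0] == 1:
        return 0.0, np.array([1.0, 0.0])
    hull_pts = points
    if points.shape[0] > 3:
        try:
            from scipy.spatial import ConvexHull

            hull_pts = points[ConvexHull(points).vertices]
        except Exception:  # collinear input, QHull failure — fall back
            hull_pts = points
    d2 = np.sum((hull_pts[:, None, :] - hull_pts[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    best = math.sqrt(d2[i, j])
    direction = hull_pts[j] - hull_pts[i]
    n = np.linalg.norm(direction)
    return best, (direction / n if n > 0 else np.array([1.0, 0.0]))


def measure_calipers(
    mask_stack: Sequence[RegionMask],
    calibration: CalibrationResult,
    thickness: float = DEFAULT_SLICE_THICKNESS,
) -> CaliperMeasurement:
    """Derive caliper dimensions from a coronal mask stack.

    Length is the maximum chord over all coronal slices, measured over
    the corner points of the occupied pixel footprints (each pixel
    occupies its full unit square, so a 10-pixel-wide block spans 10
    pixel widths, not 9 center-to-center gaps). Width is the maximum
    extent perpendicular to the length direction on the slice where
    the length is attained. Height counts occupied slices × thickness,
    matching the layer model used for the Cavalieri volume.

    Raises
    ------
    EmptyTumorError
        If no mask in the stack contains foreground pixels.
    """
    if thickness <= 0:
        raise SeriesError("slice thickness must be positive")
    if len(mask_stack) == 0:
        raise EmptyTumorError("empty mask stack")

    best_len_px = 0.0
    best_dir = None
    best_points = None
    occupied = 0
    for mask in mask_stack:
        pts = _corner_points(mask)
        if pts.shape[0] == 0:
            continue
        occupied += 1
        chord, direction = _max_chord(pts)
        if chord > best_len_px:
            best_len_px, best_dir, best_points = chord, direction, pts
    if occupied == 0:
        raise EmptyTumorError("all masks in the stack are empty")

    if best_len_px == 0.0:  # single-pixel tumor: footprint is one unit square
        best_len_px = math.sqrt(2.0)
        best_dir = np.array([math.sqrt(0.5), math.sqrt(0.5)])

    perp = np.array([-best_dir[1], best_dir[0]])
    proj = best_points @ perp
    width_px = float(proj.max() - proj.min())
    if width_px == 0.0:
        width_px = 1.0  # degenerate single-row region still spans one pixel

    p = calibration.length_ratio
    length_cm = best_len_px * p
    width_cm = width_px * p
    if width_cm > length_cm:  # numerical guard; perpendicular extent ≤ diameter
        length_cm, width_cm = width_cm, length_cm
    return CaliperMeasurement(
        length=length_cm,
        width=width_cm,
        height=occupied * thickness,
    )
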