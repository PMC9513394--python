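"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from abusvol import CalibrationResult, Contour, PhantomSpec, generate_phantom


# ---------------------------------------------------------------------------
# independent oracles (deliberately simple scalar implementations)
# ---------------------------------------------------------------------------

def point_in_polygon_even_odd(px: float, py: float, vertices: np.ndarray) -> bool:
    """Textbook scalar even-odd ray-crossing test, half-open in y and x
    (rightward ray, strict x comparison)."""
    inside = False
    n = len(vertices)
    for k in range(n):
        x1, y1 = vertices[k]
        x2, y2 = vertices[(k + 1) % n]
        if y1 == y2:
            continue
        if (y1 > py) != (y2 > py):
            xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            if px < xint:
                inside = not inside
    return inside


def brute_force_rasterize(vertices: np.ndarray, width: int, height: int) -> np.ndarray:
    """Pixel-center rasterization by per-pixel point-in-polygon tests."""
    out = np.zeros((height, width), dtype=bool)
    for j in range(height):
        for i in range(width):
            out[j, i] = point_in_polygon_even_odd(i + 0.5, j + 0.5, vertices)
    return out


def brute_force_exact_p(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact signed-rank p by enumerating all 2ⁿ sign vectors."""
    ranks = np.asarray(ranks, dtype=float)
    total = ranks.sum()
    w_obs = min(w_plus, total - w_plus)
    count = 0
    for signs in itertools.product((0.0, 1.0), repeat=ranks.size):
        w = float(np.dot(signs, ranks))
        if min(w, total - w) <= w_obs + 1e-9:
            count += 1
    return count / 2**ranks.size


def brute_force_max_chord(points: np.ndarray) -> float:
    """Maximum pairwise distance by full enumeration."""
    best = 0.0
    for p, q in itertools.combinations(points, 2):
        best = max(best, float(np.hypot(*(np.asarray(p) - np.asarray(q)))))
    return best


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def caliper_ratio_tolerance(spec: PhantomSpec) -> float:
    """Relative discretization tolerance for true/traditional ≈ π/3.

    Caliper measurement quantizes each dimension: the pixel-footprint
    convention can add up to ~1.5 px to each in-plane diameter, and the
    height rounds 2c up to a whole number of slices (≤ +1 thickness).
    These propagate linearly into the traditional volume.
    """
    a, b, c = spec.semi_axes
    p, t = spec.pixel_pitch, spec.slice_thickness
    return 1.5 * p / (2 * a) + 1.5 * p / (2 * b) + t / (2 * c) + 0.01


@pytest.fixture(scope="session")
def unit_calibration() -> CalibrationResult:
    """1 cm per pixel."""
    return CalibrationResult(length_ratio=1.0, area_ratio=1.0)


@pytest.fixture(scope="session")
def tenth_cm_calibration() -> CalibrationResult:
    """0.1 cm per pixel (coarse clinical-scale pitch)."""
    return CalibrationResult(length_ratio=0.1, area_ratio=0.01)


@pytest.fixture
def square_contour() -> Contour:
    return Contour([(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)])


@pytest.fixture(scope="session")
def ellipsoid_realization():
    """A moderately fine ellipsoid phantom shared across tests."""
    spec = PhantomSpec(
        shape="ellipsoid",
        semi_axes=(1.0, 0.8, 0.6),
        pixel_pitch=0.01,
        slice_thickness=0.02,
    )
    return spec, generate_phantom(spec)
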