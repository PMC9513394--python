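"""Synthetic tumor phantoms with analytically known volume.

Real ABUS data cannot ship with the package, so every upstream operation
is exercised against phantoms: 3-D shapes sectioned into coronal mask
stacks at a fixed slice spacing, with ground-truth volume and caliper
dimensions known by construction.

Two shapes are provided. ``ellipsoid`` has semi-axes ``(a, b, c)`` cm —
``a, b`` in the coronal plane, ``c`` anteroposterior — and volume
(4/3)πabc. ``perturbed_ellipsoid`` multiplies each coronal radius by a
band-limited random harmonic series ρ(θ) = 1 + Σₘ εₘ cos(mθ + φₘ),
emulating irregular lesion outlines while keeping the volume in closed
form: every coronal area scales by (1 + Σₘ εₘ²/2), hence so does the
volume. Observer outlining variability is modelled separately by
:func:`perturb_contour`, which displaces contour vertices radially with
smoothed Gaussian noise.

Sizes mirror the clinical inclusion range (long diameter 1–5 cm); the
default slice thickness is the ABUS coronal spacing of 0.1 cm.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .calibration import CalibrationResult
from .errors import PhantomError, RenderError
from .planimetry import Contour, RegionMask
from .volumetry import DEFAULT_SLICE_THICKNESS

__all__ = [
    "PhantomSpec",
    "PhantomRealization",
    "generate_phantom",
    "perturb_contour",
    "render_slice_image",
    "extract_region_mask",
]

#: gray level of the tumor region in rendered images
REGION_LEVEL = 200
#: gray level of the scale bar in rendered images
BAR_LEVEL = 255


@dataclass(frozen=True)
class PhantomSpec:
    """Parametric description of a synthetic tumor.

    Parameters
    ----------
    shape
        ``"ellipsoid"`` or ``"perturbed_ellipsoid"``.
    semi_axes
        ``(a, b, c)`` in cm; ``a, b`` span the coronal plane, ``c`` the
        anteroposterior (slice-stacking) direction.
    pixel_pitch
        In-plane pixel size, cm/px.
    slice_thickness
        Coronal inter-slice spacing, cm.
    perturbation_amplitude
        RMS fractional radial perturbation of the harmonic series
        (ignored for plain ellipsoids); must lie in [0, 0.5).
    smoothness
        Highest harmonic retained in the perturbation series.
    seed
        Seed for the harmonic coefficients; identical specs generate
        identical realizations.
    """

    shape: str = "ellipsoid"
    semi_axes: tuple[float, float, float] = (1.0, 1.0, 1.0)
    pixel_pitch: float = 0.01
    slice_thickness: float = DEFAULT_SLICE_THICKNESS
    perturbation_amplitude: float = 0.0
    smoothness: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shape not in ("ellipsoid", "perturbed_ellipsoid"):
            raise PhantomError(f"unknown shape {self.shape!r}")
        if any(s <= 0 for s in self.semi_axes):
            raise PhantomError("semi-axes must be positive")
        if not self.pixel_pitch > 0 or not self.slice_thickness > 0:
            raise PhantomError("pixel pitch and slice thickness must be positive")
        if not 0 <= self.perturbation_amplitude < 0.5:
            raise PhantomError("perturbation amplitude must lie in [0, 0.5)")
        if self.smoothness < 1:
            raise PhantomError("smoothness (harmonic cutoff) must be ≥ 1")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path | None = None) -> str:
        import yaml

        payload = yaml.safe_dump(
            {
                "shape": self.shape,
                "semi_axes": list(self.semi_axes),
                "pixel_pitch": self.pixel_pitch,
                "slice_thickness": self.slice_thickness,
                "perturbation_amplitude": self.perturbation_amplitude,
                "smoothness": self.smoothness,
                "seed": self.seed,
            }
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PhantomSpec":
        import yaml

        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        obj = yaml.safe_load(text)
        obj["semi_axes"] = tuple(obj["semi_axes"])
        return cls(**obj)


@dataclass(frozen=True)
class PhantomRealization:
    """A sectioned phantom: coronal mask stack plus ground truth."""

    mask_stack: tuple
    true_volume: float
    true_calipers: tuple[float, float, float]
    spec: PhantomSpec = field(repr=False, default=None)

    def __post_init__(self) -> None:
        if not self.mask_stack:
            raise PhantomError("realization has an empty mask stack")
        if not self.true_volume > 0:
            raise PhantomError("true volume must be positive")

    def slice_areas(self, calibration: CalibrationResult) -> np.ndarray:
        """Per-slice areas in cm² under the given calibration."""
        return np.array(
            [m.pixel_count * calibration.area_ratio for m in self.mask_stack]
        )


def _harmonics(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Seeded harmonic amplitudes and phases for the perturbed shape.

    Coefficients are scaled so the RMS of ρ(θ) − 1 equals the requested
    amplitude, then clipped so ρ stays positive everywhere.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.smoothness
    eps = rng.normal(size=m)
    phases = rng.uniform(0, 2 * math.pi, size=m)
    rms = math.sqrt(float(np.sum(eps**2)) / 2)
    if rms > 0 and spec.perturbation_amplitude > 0:
        eps = eps * (spec.perturbation_amplitude / rms)
    else:
        eps = np.zeros(m)
    # worst-case dip: 1 − Σ|εₘ|; keep strictly positive radius
    overshoot = float(np.abs(eps).sum())
    if overshoot >= 0.9:
        eps *= 0.9 / overshoot
    return eps, phases


def _rho(theta: np.ndarray, eps: np.ndarray, phases: np.ndarray) -> np.ndarray:
    rho = np.ones_like(theta)
    for m, (e, ph) in enumerate(zip(eps, phases), start=1):
        rho = rho + e * np.cos(m * theta + ph)
    return rho


def generate_phantom(spec: PhantomSpec) -> PhantomRealization:
    """Section a phantom into coronal masks at the spec's spacing.

    Slice planes are placed at the mid-heights of contiguous layers
    covering ``[-c, c]``: layer ``k`` is evaluated at
    ``z = -c + (k + 1/2)·thickness``, matching the layer model of the
    Cavalieri sum. A pixel is set iff its center lies inside the shape's
    cross-section at that plane.
    """
    a, b, c = spec.semi_axes
    p = spec.pixel_pitch
    t = spec.slice_thickness
    if 2 * a < p or 2 * b < p or 2 * c < t:
        raise PhantomError("phantom smaller than one pixel or one slice")

    if spec.shape == "perturbed_ellipsoid":
        eps, phases = _harmonics(spec)
    else:
        eps = np.zeros(spec.smoothness)
        phases = np.zeros(spec.smoothness)

    # raster large enough for the worst-case perturbed radius
    growth = 1.0 + float(np.abs(eps).sum())
    half_w = a * growth + p
    half_h = b * growth + p
    width = int(math.ceil(2 * half_w / p))
    height = int(math.ceil(2 * half_h / p))
    xs = (np.arange(width) + 0.5) * p - width * p / 2   # (W,) cm
    ys = (np.arange(height) + 0.5) * p - height * p / 2  # (H,) cm

    n_slices = int(math.ceil(2 * c / t))
    masks = []
    any_filled = False
    for k in range(n_slices):
        z = -c + (k + 0.5) * t
        frac = 1.0 - (z / c) ** 2
        if frac <= 0:
            masks.append(RegionMask(np.zeros((height, width), dtype=bool)))
            continue
        s = math.sqrt(frac)
        ax, bx = a * s, b * s
        xn = xs[None, :] / ax
        yn = ys[:, None] / bx
        r = np.hypot(xn, yn)
        if eps.any():
            theta = np.arctan2(yn, xn)
            inside = r <= _rho(theta, eps, phases)
        else:
            inside = r <= 1.0
        if inside.any():
            any_filled = True
        masks.append(RegionMask(inside))
    if not any_filled:
        raise PhantomError("phantom produced no foreground voxels")

    shape_factor = 1.0 + float(np.sum(eps**2)) / 2  # ∮ρ²dθ / 2π
    true_volume = shape_factor * (4.0 / 3.0) * math.pi * a * b * c
    true_calipers = _true_calipers(a, b, c, eps, phases)
    return PhantomRealization(
        mask_stack=tuple(masks),
        true_volume=true_volume,
        true_calipers=true_calipers,
        spec=spec,
    )


def _true_calipers(
    a: float, b: float, c: float, eps: np.ndarray, phases: np.ndarray
) -> tuple[float, float, float]:
    """Ground-truth caliper dimensions of the analytic shape.

    For a plain ellipsoid these are the axis lengths. For the perturbed
    shape the central coronal contour is sampled densely and its maximum
    chord (and perpendicular extent) taken.
    """
    if not eps.any():
        hi, lo = max(a, b), min(a, b)
        return (2 * hi, 2 * lo, 2 * c)
    theta = np.linspace(0, 2 * math.pi, 4096, endpoint=False)
    rho = _rho(theta, eps, phases)
    pts = np.column_stack([a * rho * np.cos(theta), b * rho * np.sin(theta)])
    d2 = None
    try:
        from scipy.spatial import ConvexHull

        pts = pts[ConvexHull(pts).vertices]
    except Exception:
        pass
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    i, j = np.unravel_index(np.argmax(d2), d2.shape)
    length = math.sqrt(float(d2[i, j]))
    u = pts[j] - pts[i]
    u = u / np.linalg.norm(u)
    proj = pts @ np.array([-u[1], u[0]])
    width = float(proj.max() - proj.min())
    return (max(length, width), min(length, width), 2 * c)


def voxel_volume_oracle(spec: PhantomSpec, refine: int = 4) -> float:
    """Numerical volume by re-sectioning at ``refine×`` finer pitch and
    slice spacing — a discretization-dominated cross-check on
    ``true_volume`` for tests and convergence studies."""
    fine = PhantomSpec(
        shape=spec.shape,
        semi_axes=spec.semi_axes,
        pixel_pitch=spec.pixel_pitch / refine,
        slice_thickness=spec.slice_thickness / refine,
        perturbation_amplitude=spec.perturbation_amplitude,
        smoothness=spec.smoothness,
        seed=spec.seed,
    )
    real = generate_phantom(fine)
    area_px = fine.pixel_pitch**2
    return float(
        sum(m.pixel_count for m in real.mask_stack) * area_px * fine.slice_thickness
    )


def perturb_contour(
    contour: Contour,
    amplitude: float,
    correlation_length: int = 5,
    seed: int = 0,
) -> Contour:
    """Displace contour vertices radially with smoothed Gaussian noise.

    Models inter-observer outlining variability: each vertex moves along
    the ray from the contour centroid by a zero-mean Gaussian amount
    (SD = ``amplitude`` pixels) smoothed circularly over
    ``correlation_length`` vertices so neighbouring displacements are
    correlated, as a human tracing error would be.

    If the displaced outline self-intersects, the draw is retried with
    the amplitude damped by 30% per attempt; after 10 attempts the last
    (possibly self-intersecting) contour is returned with a warning.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude == 0:
        return contour
    v = contour.vertices
    centroid = v.mean(axis=0)
    radial = v - centroid
    norms = np.linalg.norm(radial, axis=1)
    norms[norms == 0] = 1.0
    unit = radial / norms[:, None]

    rng = np.random.default_rng(seed)
    amp = amplitude
    window = max(int(correlation_length), 1)
    kernel = np.ones(window) / window
    for attempt in range(10):
        noise = rng.normal(size=len(v))
        if window > 1:
            # circular moving average, re-scaled back to unit variance
            padded = np.concatenate([noise[-(window - 1):], noise])
            noise = np.convolve(padded, kernel, mode="valid")
            sd = noise.std()
            if sd > 0:
                noise = noise / sd
        candidate = Contour(v + unit * (amp * noise)[:, None])
        if candidate.is_simple():
            return candidate
        amp *= 0.7
    warnings.warn(
        "perturbed contour still self-intersects after 10 damped retries",
        stacklevel=2,
    )
    return candidate


def render_slice_image(
    mask: RegionMask,
    calibration: CalibrationResult,
    scalebar_cm: float = 5.0,
    margin: int = 6,
) -> np.ndarray:
    """Render a grayscale slice image with the region and a scale bar.

    The region is drawn at gray level ``REGION_LEVEL`` and a horizontal
    scale bar of ``scalebar_cm`` physical length at ``BAR_LEVEL`` on the
    second-to-last row of an appended bottom margin, starting at column
    1. Round-tripping through :func:`extract_region_mask` recovers the
    mask's pixel count exactly; reading the bar with
    :func:`abusvol.calibration.detect_scale_bar` recovers the pixel
    pitch (exactly when the bar spans a whole number of pixels).
    """
    if scalebar_cm <= 0:
        raise RenderError("scale bar length must be positive")
    bar_px = int(round(scalebar_cm / calibration.length_ratio))
    h, w = mask.bitmap.shape
    if bar_px > w - 2:
        raise RenderError(
            f"scale bar of {bar_px} px does not fit in a {w}-px-wide image"
        )
    img = np.zeros((h + margin, w), dtype=np.uint8)
    img[:h][mask.bitmap] = REGION_LEVEL
    img[h + margin - 2, 1 : 1 + bar_px] = BAR_LEVEL
    return img


def extract_region_mask(image: np.ndarray) -> RegionMask:
    """Recover the tumor region from a rendered slice image."""
    return RegionMask(np.asarray(image) == REGION_LEVEL)


def export_realization(
    realization: PhantomRealization,
    out_dir: str | Path,
    calibration: CalibrationResult | None = None,
) -> Path:
    """Write a mask-stack PNG series and a per-slice area CSV."""
    from .volumetry import SliceSeries

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, m in enumerate(realization.mask_stack):
        m.to_png(out / f"slice_{i:04d}.png")
    if calibration is None:
        calibration = CalibrationResult(
            length_ratio=realization.spec.pixel_pitch,
            area_ratio=realization.spec.pixel_pitch**2,
        )
    series = SliceSeries(
        realization.slice_areas(calibration),
        thickness=realization.spec.slice_thickness,
    )
    series.to_csv(out / "areas.csv")
    return out
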