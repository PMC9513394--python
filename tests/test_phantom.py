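"""Synthetic phantoms: generation, observer noise, rendering."""

import math

import numpy as np
import pytest

from abusvol import (
    CalibrationResult,
    Contour,
    PhantomSpec,
    SliceSeries,
    cavalieri_volume,
    detect_scale_bar,
    extract_region_mask,
    generate_phantom,
    perturb_contour,
    pixel_area_ratio_from_bar,
    rasterize_contour,
    render_slice_image,
    cross_section_area,
)
from abusvol.errors import PhantomError, RenderError
from abusvol.phantom import export_realization, voxel_volume_oracle


def _pixel_volume(spec, real):
    cal = CalibrationResult(spec.pixel_pitch, spec.pixel_pitch**2)
    return cavalieri_volume(
        SliceSeries(real.slice_areas(cal), spec.slice_thickness)
    )


class TestGeneratePhantom:
    def test_sphere_volume_within_one_percent(self):
        spec = PhantomSpec(semi_axes=(1.0, 1.0, 1.0), pixel_pitch=0.01, slice_thickness=0.01)
        real = generate_phantom(spec)
        assert real.true_volume == pytest.approx(4 * math.pi / 3, rel=1e-12)
        assert _pixel_volume(spec, real) == pytest.approx(real.true_volume, rel=0.01)

    def test_unit_ellipsoid_equals_sphere(self):
        sphere = generate_phantom(PhantomSpec(semi_axes=(1.0, 1.0, 1.0), pixel_pitch=0.02))
        ellip = generate_phantom(
            PhantomSpec(shape="ellipsoid", semi_axes=(1.0, 1.0, 1.0), pixel_pitch=0.02)
        )
        assert sphere.true_volume == ellip.true_volume
        for m1, m2 in zip(sphere.mask_stack, ellip.mask_stack):
            assert np.array_equal(m1.bitmap, m2.bitmap)

    def test_zero_amplitude_perturbation_is_plain_ellipsoid(self):
        base = PhantomSpec(semi_axes=(1.0, 0.8, 0.6), pixel_pitch=0.02, seed=5)
        perturbed = PhantomSpec(
            shape="perturbed_ellipsoid",
            semi_axes=(1.0, 0.8, 0.6),
            pixel_pitch=0.02,
            perturbation_amplitude=0.0,
            seed=5,
        )
        r1, r2 = generate_phantom(base), generate_phantom(perturbed)
        assert r1.true_volume == r2.true_volume
        for m1, m2 in zip(r1.mask_stack, r2.mask_stack):
            assert np.array_equal(m1.bitmap, m2.bitmap)

    def test_seeded_determinism(self):
        spec = PhantomSpec(
            shape="perturbed_ellipsoid",
            semi_axes=(1.0, 0.9, 0.7),
            pixel_pitch=0.02,
            perturbation_amplitude=0.2,
            seed=99,
        )
        r1, r2 = generate_phantom(spec), generate_phantom(spec)
        assert r1.true_volume == r2.true_volume
        for m1, m2 in zip(r1.mask_stack, r2.mask_stack):
            assert np.array_equal(m1.bitmap, m2.bitmap)

    def test_degenerate_phantom_rejected(self):
        with pytest.raises(PhantomError):
            generate_phantom(PhantomSpec(semi_axes=(0.001, 0.001, 0.001), pixel_pitch=0.01))

    def test_invalid_specs_rejected(self):
        with pytest.raises(PhantomError):
            PhantomSpec(shape="cube")
        with pytest.raises(PhantomError):
            PhantomSpec(perturbation_amplitude=0.6)
        with pytest.raises(PhantomError):
            PhantomSpec(semi_axes=(1.0, -1.0, 1.0))

    def test_perturbed_volume_matches_voxel_oracle(self):
        spec = PhantomSpec(
            shape="perturbed_ellipsoid",
            semi_axes=(0.8, 0.6, 0.5),
            pixel_pitch=0.02,
            slice_thickness=0.1,
            perturbation_amplitude=0.15,
            seed=3,
        )
        real = generate_phantom(spec)
        oracle = voxel_volume_oracle(spec, refine=4)
        assert real.true_volume == pytest.approx(oracle, rel=0.01)

    def test_yaml_round_trip(self, tmp_path):
        spec = PhantomSpec(
            shape="perturbed_ellipsoid",
            semi_axes=(1.2, 0.8, 0.5),
            perturbation_amplitude=0.1,
            seed=17,
        )
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        assert PhantomSpec.from_yaml(path) == spec


class TestParameterRecovery:
    def test_ellipsoid_volume_and_caliper_bias(self):
        """Across seeded ellipsoids spanning the clinical 1–5 cm range,
        the pixel method recovers the analytic volume within 2% and the
        caliper formula shows its closed-form ellipsoid bias 3/π − 1."""
        from abusvol import measure_calipers, traditional_volume

        from conftest import caliper_ratio_tolerance

        rng = np.random.default_rng(7)
        for _ in range(8):
            a = rng.uniform(0.5, 2.5)
            b = a * rng.uniform(0.5, 1.0)
            c = b * rng.uniform(0.5, 1.0)
            spec = PhantomSpec(semi_axes=(a, b, c), pixel_pitch=0.02, slice_thickness=0.05)
            real = generate_phantom(spec)
            pixel_vol = _pixel_volume(spec, real)
            assert pixel_vol == pytest.approx(real.true_volume, rel=0.02)
            cal = CalibrationResult(0.02, 4e-4)
            trad = traditional_volume(measure_calipers(real.mask_stack, cal, 0.05))
            assert real.true_volume / trad == pytest.approx(
                math.pi / 3, rel=caliper_ratio_tolerance(spec)
            )


class TestPerturbContour:
    @staticmethod
    def _circle(n=120, r=100.0, center=150.0):
        theta = np.linspace(0, 2 * math.pi, n, endpoint=False)
        return Contour(
            np.column_stack(
                [center + r * np.cos(theta), center + r * np.sin(theta)]
            )
        )

    def test_zero_amplitude_is_identity(self):
        c = self._circle()
        assert perturb_contour(c, 0.0) is c

    def test_seeded_determinism(self):
        c = self._circle()
        p1 = perturb_contour(c, 2.0, 5, seed=11)
        p2 = perturb_contour(c, 2.0, 5, seed=11)
        assert np.allclose(p1.vertices, p2.vertices)
        p3 = perturb_contour(c, 2.0, 5, seed=12)
        assert not np.allclose(p1.vertices, p3.vertices)

    def test_noise_scale_drives_area_spread(self):
        """Enclosed-area spread is small (< 5% relative SD) at 2-px
        amplitude on a 100-px circle, and grows with amplitude."""
        c = self._circle()
        spreads = []
        for amplitude in (2.0, 6.0):
            areas = []
            for seed in range(200):
                p = perturb_contour(c, amplitude, 5, seed=seed)
                areas.append(rasterize_contour(p, 300, 300).pixel_count)
            areas = np.array(areas, dtype=float)
            spreads.append(areas.std(ddof=1) / areas.mean())
        assert spreads[0] < 0.05
        assert spreads[1] > spreads[0]

    def test_interobserver_sd_grows_with_amplitude(self):
        """SD of paired pixel-count differences between two independent
        observers increases monotonically with outlining noise."""
        c = self._circle(n=90)
        sds = []
        for amplitude in (1.0, 3.0, 8.0):
            diffs = []
            for seed in range(60):
                a1 = rasterize_contour(
                    perturb_contour(c, amplitude, 5, seed=2 * seed), 300, 300
                ).pixel_count
                a2 = rasterize_contour(
                    perturb_contour(c, amplitude, 5, seed=2 * seed + 1), 300, 300
                ).pixel_count
                diffs.append(a1 - a2)
            sds.append(np.std(diffs, ddof=1))
        assert sds[0] < sds[1] < sds[2]


class TestRenderSliceImage:
    def test_region_round_trip(self, square_contour, tenth_cm_calibration):
        mask = rasterize_contour(square_contour, 60, 20)
        img = render_slice_image(mask, tenth_cm_calibration, scalebar_cm=5.0)
        assert extract_region_mask(img).pixel_count == mask.pixel_count

    def test_scale_bar_round_trip(self, square_contour):
        pitch = 0.01
        cal = CalibrationResult(pitch, pitch**2)
        mask = rasterize_contour(square_contour, 600, 30)
        img = render_slice_image(mask, cal, scalebar_cm=5.0)
        bar_px = detect_scale_bar(img)
        recovered = pixel_area_ratio_from_bar(bar_px, 5.0)
        assert recovered.length_ratio == pytest.approx(pitch, rel=1e-9)

    def test_bar_too_long_rejected(self, square_contour, tenth_cm_calibration):
        mask = rasterize_contour(square_contour, 20, 20)
        with pytest.raises(RenderError):
            render_slice_image(mask, tenth_cm_calibration, scalebar_cm=5.0)

    def test_disc_end_to_end(self):
        """Render → calibrate from the bar → re-outline → pixel area ≈ πR²."""
        pitch = 0.01
        radius_cm = 1.2
        r_px = radius_cm / pitch
        center = r_px + 5
        theta = np.linspace(0, 2 * math.pi, 720, endpoint=False)
        contour = Contour(
            np.column_stack(
                [center + r_px * np.cos(theta), center + r_px * np.sin(theta)]
            )
        )
        n = int(2 * center) + 10
        n = max(n, int(5.0 / pitch) + 4)  # room for the 5-cm bar
        mask = rasterize_contour(contour, n, int(2 * center) + 10)
        cal = CalibrationResult(pitch, pitch**2)
        img = render_slice_image(mask, cal, scalebar_cm=5.0)
        recovered_cal = pixel_area_ratio_from_bar(detect_scale_bar(img), 5.0)
        count = extract_region_mask(img).pixel_count
        area = cross_section_area(count, recovered_cal)
        assert area == pytest.approx(math.pi * radius_cm**2, rel=0.005)


def test_export_realization(tmp_path):
    spec = PhantomSpec(semi_axes=(0.5, 0.4, 0.3), pixel_pitch=0.02, slice_thickness=0.1)
    real = generate_phantom(spec)
    out = export_realization(real, tmp_path / "phantom")
    pngs = sorted(out.glob("slice_*.png"))
    assert len(pngs) == len(real.mask_stack)
    series = SliceSeries.from_csv(out / "areas.csv")
    assert cavalieri_volume(series) == pytest.approx(real.true_volume, rel=0.05)
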