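"""En face projection, Eq.-style differentials, ROI statistics, OD mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhodoct import (
    AdaptationState,
    BoundaryMap,
    DifferentialImage,
    OCTVolume,
    ScanParams,
    apply_adaptation,
    average_alines,
    bleach_energy_per_point,
    build_phantom,
    detect_bleach_pattern,
    detect_isos,
    differential_image,
    enface_projection,
    estimate_rhodopsin_od,
    expected_volume,
    percent_lower,
    roi_stats,
    simulate_volume,
)
from .conftest import delta_od_520


class TestEnFace:
    def test_band_of_one_is_the_isos_row(self, rng):
        vol = OCTVolume(rng.random((4, 8, 32)).astype(np.float32), 2.0)
        b = BoundaryMap(isos_z=rng.integers(5, 25, size=(4, 8)))
        enf = enface_projection(vol, b, band_extent=1)
        rows = np.take_along_axis(vol.intensity, b.isos_z[..., None], axis=2)[..., 0]
        np.testing.assert_allclose(enf.value, rows, rtol=1e-7)

    def test_matches_brute_force_summation(self, rng):
        vol = OCTVolume(rng.random((5, 7, 40)).astype(np.float32), 2.0)
        b = BoundaryMap(isos_z=rng.integers(0, 35, size=(5, 7)))
        band = 12
        enf = enface_projection(vol, b, band)
        brute = np.zeros((5, 7))
        for y in range(5):
            for x in range(7):
                for z in range(b.isos_z[y, x], min(b.isos_z[y, x] + band, 40)):
                    brute[y, x] += vol.intensity[y, x, z]
        np.testing.assert_allclose(enf.value, brute, rtol=1e-6)
        assert enf.truncated  # some bands hit the deep edge

    def test_dark_projection_dimmer_than_light(self, dark_light, small_params):
        """Rhodopsin absorption makes every photoreceptor-bearing A-line of
        the dark-adapted projection weaker."""
        dark, light = dark_light
        vd = expected_volume(dark, small_params)
        vl = expected_volume(light, small_params)
        b = detect_isos(vd)
        ed = enface_projection(vd, b, 40).value
        el = enface_projection(vl, b, 40).value
        assert (ed < el).all()

    def test_nonpositive_band_rejected(self, rng):
        vol = OCTVolume(rng.random((2, 2, 16)), 2.0)
        with pytest.raises(ValueError, match="band_extent"):
            enface_projection(vol, BoundaryMap(isos_z=np.zeros((2, 2), int)), 0)


class TestDifferential:
    @pytest.mark.parametrize("norm", ["relative", "log_density"])
    def test_identical_images_give_zero(self, norm, rng):
        img = rng.random((16, 16))
        d = differential_image(img, img, norm)
        np.testing.assert_allclose(d.value, 0.0, atol=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            differential_image(np.zeros((2, 3)), np.zeros((3, 2)))

    def test_nonpositive_floor_rejected(self):
        with pytest.raises(ValueError, match="floor"):
            differential_image(np.ones((2, 2)), np.ones((2, 2)), floor=0.0)

    def test_log_density_equals_double_pass_od(self, dark_light, small_params):
        """On noise-free volumes the log-density differential below the OS is
        exactly twice the rhodopsin OD change at the probe."""
        dark, light = dark_light
        vd = expected_volume(dark, small_params).intensity
        vl = expected_volume(light, small_params).intensity
        z0 = int((dark.top_offset_um + 175.0) / small_params.z_pitch)  # RPE/choroid
        z1 = int((dark.top_offset_um + 210.0) / small_params.z_pitch)
        d = differential_image(vd[0, :, z0:z1], vl[0, :, z0:z1], "log_density", plane="xz")
        np.testing.assert_allclose(d.value, 2.0 * delta_od_520(dark), rtol=1e-4)

    def test_relative_normalization_bounded_by_one(self, rng):
        d = differential_image(rng.random((8, 8)), rng.random((8, 8)))
        assert d.value.max() <= 1.0


class TestDepthProfileAndROI:
    def test_constant_differential_profiles_flat(self):
        d = DifferentialImage(np.full((16, 64), 0.37), plane="xz")
        prof = average_alines(d)
        np.testing.assert_allclose(prof.value, 0.37)

    def test_all_excluded_rejected(self):
        d = DifferentialImage(np.zeros((4, 8)), plane="xz")
        with pytest.raises(ValueError, match="excluded"):
            average_alines(d, exclude_mask=np.ones(4, bool))

    def test_single_pixel_roi(self):
        img = DifferentialImage(np.arange(12.0).reshape(3, 4), plane="xy")
        roi = np.zeros((3, 4), bool)
        roi[1, 2] = True
        s = roi_stats(img, roi, "pixel")
        assert (s.mean, s.sd, s.n_pixels) == (6.0, 0.0, 1)

    def test_empty_roi_rejected(self):
        img = DifferentialImage(np.zeros((3, 4)), plane="xy")
        with pytest.raises(ValueError, match="empty"):
            roi_stats(img, np.zeros((3, 4), bool))

    def test_population_sd_convention(self, rng):
        img = rng.random((10, 10))
        s = roi_stats(DifferentialImage(img, "xy"), np.ones((10, 10), bool))
        assert s.sd == pytest.approx(img.std(ddof=0))

    def test_inner_retina_percent_difference(self):
        """Printed inner-retina means: in-strip 0.0094 vs outside 0.0097 is
        about 3% lower (1 significant figure)."""
        assert round(percent_lower(0.0094, 0.0097)) == 3


class TestRhodopsinMap:
    def test_fully_bleached_field_has_zero_od(self, dark_light, small_params):
        _, light = dark_light
        vl = expected_volume(light, small_params)
        b = detect_isos(vl)
        e1 = enface_projection(vl, b, 40)
        e2 = enface_projection(vl, b, 40)
        rho = estimate_rhodopsin_od(e1, e2)
        np.testing.assert_allclose(rho.od_estimate, 0.0, atol=1e-9)

    def test_band_mismatch_rejected(self, dark_light, small_params):
        dark, light = dark_light
        vd = expected_volume(dark, small_params)
        b = detect_isos(vd)
        with pytest.raises(ValueError, match="band"):
            estimate_rhodopsin_od(
                enface_projection(vd, b, 20), enface_projection(vd, b, 30)
            )

    def test_noise_free_parameter_recovery(self, dark_light, small_params):
        """With the band placed below the outer segments the recovered OD
        matches the ground-truth probe-wavelength OD within 10%."""
        dark, light = dark_light
        vd = expected_volume(dark, small_params)
        vl = expected_volume(light, small_params)
        b = detect_isos(vd)
        sub = BoundaryMap(isos_z=b.isos_z + 20)  # OS (15 px) + PSF margin
        ed = enface_projection(vd, sub, 25)
        el = enface_projection(vl, sub, 25)
        rho = estimate_rhodopsin_od(ed, el)
        truth = delta_od_520(dark)
        assert np.median(rho.od_estimate) == pytest.approx(truth, rel=0.10)


class TestBleachPattern:
    def test_uniform_differential_warns_empty(self):
        d = DifferentialImage(np.full((32, 32), 0.2), plane="xy")
        with pytest.warns(UserWarning, match="uniform|unimodal"):
            mask = detect_bleach_pattern(d)
        assert not mask.any()

    def test_edge_strip_detected_contiguously(self, rng):
        img = np.full((40, 100), 0.5) + 0.02 * rng.standard_normal((40, 100))
        img[:, :20] = 0.02 + 0.02 * rng.standard_normal((40, 20))
        mask = detect_bleach_pattern(DifferentialImage(img, "xy"))
        cols = mask.mean(axis=0) > 0.5
        assert cols[0]  # touches the field edge
        runs = np.diff(np.flatnonzero(cols))
        assert (runs == 1).all()  # contiguous

    def test_zero_contrast_null(self):
        """With no rhodopsin, dark and light scans differ only by speckle
        decorrelation noise: the differential mean is a few percent."""
        params = ScanParams(n_x=96, n_y=24, n_z=256, seed=11)
        ph = build_phantom({"map_shape": (24, 96), "rhodopsin_od_peak": 0.0})
        vd = simulate_volume(apply_adaptation(ph, AdaptationState("dark")), params, acquisition=0)
        vl = simulate_volume(apply_adaptation(ph, AdaptationState("light")), params, acquisition=1)
        b = detect_isos(vd)
        band = b.band_extent_to_bottom()
        d = differential_image(enface_projection(vd, b, band), enface_projection(vl, b, band))
        assert np.abs(np.mean(d.value)) < 0.03


class TestDosimetry:
    def test_pattern_bleach_energy(self):
        """800 uW at 10k points/s, two raster passes -> 160 nJ per point."""
        assert bleach_energy_per_point(800e-6, 10_000, 2) == pytest.approx(160e-9)

    def test_unit_identity(self):
        assert bleach_energy_per_point(1.0, 1.0, 1) == 1.0

    def test_probe_beam_dose(self):
        """240 uW probe at the 64k lines/s A-line rate delivers 3.75 nJ."""
        assert bleach_energy_per_point(240e-6, 64_000, 1) == pytest.approx(3.75e-9)

    @pytest.mark.parametrize("bad", [(-1, 1, 1), (1, 0, 1), (1, 1, 0)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(ValueError):
            bleach_energy_per_point(*bad)

    @settings(derandomize=True, max_examples=25)
    @given(
        power=st.floats(1e-6, 1.0),
        rate=st.floats(1.0, 1e6),
        passes=st.integers(1, 10),
    )
    def test_energy_linear_in_passes_and_power(self, power, rate, passes):
        one = bleach_energy_per_point(power, rate, 1)
        assert bleach_energy_per_point(power, rate, passes) == pytest.approx(passes * one)
        assert bleach_energy_per_point(2 * power, rate, passes) == pytest.approx(
            2 * passes * one
        )
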