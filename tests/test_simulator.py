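"""Forward model: Beer-Lambert expectation, speckle statistics, raw spectra."""

import numpy as np
import pytest

from rhodoct import (
    AdaptationState,
    ScanParams,
    apply_adaptation,
    build_phantom,
    expected_aline,
    expected_volume,
    simulate_volume,
    synthesize_spectra,
)
from rhodoct.phantom import PhantomError
from rhodoct.reconstruct import CalibrationProfile, reconstruct_aline
from rhodoct.simulate import (
    SourceSpectrum,
    max_depth_um,
    phantom_reflectors,
    spectra_from_reflectors,
)
from .conftest import delta_od_520


def _choroid_rows(phantom, params, margin_um=12.0):
    """Depth indices safely inside the choroid (away from boundaries)."""
    top, bot = phantom.layer_interval_um("choroid")
    off = phantom.top_offset_um
    z0 = int((off + top + margin_um) / params.z_pitch)
    z1 = int((off + bot - margin_um) / params.z_pitch)
    return slice(z0, z1)


class TestExpectedAline:
    def test_double_pass_shadow_in_choroid(self, dark_light, small_params, source):
        """Dark/light intensity ratio below the OS equals the double-pass
        Beer-Lambert transmission change at the probe wavelength."""
        dark, light = dark_light
        pd = expected_aline(dark, source, 10.0, 10.0, small_params)
        pl = expected_aline(light, source, 10.0, 10.0, small_params)
        rows = _choroid_rows(dark, small_params)
        expected = 10.0 ** (-2.0 * delta_od_520(dark))
        np.testing.assert_allclose(pd[rows] / pl[rows], expected, rtol=1e-5)

    def test_no_differential_above_isos(self, dark_light, small_params, source):
        dark, light = dark_light
        pd = expected_aline(dark, source, 10.0, 10.0, small_params)
        pl = expected_aline(light, source, 10.0, 10.0, small_params)
        isos_px = int(dark.isos_depth_um()[0, 0] / small_params.z_pitch)
        # stay clear of the axial PSF tail of the OS absorption edge
        np.testing.assert_allclose(pd[: isos_px - 10], pl[: isos_px - 10], rtol=1e-6)

    def test_melanin_shadow_attenuates_pigmented_choroid(self, small_params, source):
        """The pigmented choroid is darker than the albino one by the melanin
        double-pass factor accumulated above each depth."""
        kw = {"map_shape": (small_params.n_y, small_params.n_x), "curvature_um": 0.0}
        alb = apply_adaptation(build_phantom({**kw, "pigmented": False}), AdaptationState("light"))
        pig = apply_adaptation(build_phantom({**kw, "pigmented": True}), AdaptationState("light"))
        pa = expected_aline(alb, source, 10.0, 10.0, small_params, blur=False)
        pp = expected_aline(pig, source, 10.0, 10.0, small_params, blur=False)
        top, _ = pig.layer_interval_um("choroid")
        rows = _choroid_rows(pig, small_params)
        zc = (np.arange(small_params.n_z)[rows] + 0.5) * small_params.z_pitch
        frac_into_choroid = (zc - pig.top_offset_um - top) / 50.0
        od_above = pig.melanin_od * (1.0 + frac_into_choroid)  # full RPE + partial choroid
        np.testing.assert_allclose(pp[rows] / pa[rows], 10.0 ** (-2.0 * od_above), rtol=1e-4)

    def test_requires_adaptation_state(self, small_phantom, small_params, source):
        with pytest.raises(PhantomError, match="adaptation"):
            expected_aline(small_phantom, source, 10.0, 10.0, small_params)

    def test_sub_os_energy_monotone_in_od(self, small_params, source):
        energies = []
        for od in (0.1, 0.2, 0.3):
            ph = build_phantom(
                {"map_shape": (small_params.n_y, small_params.n_x), "rhodopsin_od_peak": od}
            )
            ph = apply_adaptation(ph, AdaptationState("dark"))
            p = expected_aline(ph, source, 10.0, 10.0, small_params)
            isos_px = int(ph.isos_depth_um()[0, 0] / small_params.z_pitch)
            energies.append(p[isos_px:].sum())
        assert energies[0] > energies[1] > energies[2]


class TestSpeckle:
    def test_bit_for_bit_reproducible(self, dark_light, small_params):
        _, light = dark_light
        v1 = simulate_volume(light, small_params, acquisition=1)
        v2 = simulate_volume(light, small_params, acquisition=1)
        np.testing.assert_array_equal(v1.intensity, v2.intensity)

    def test_speckle_mean_matches_expectation(self, dark_light, small_params):
        """Speckle intensity is exponential with mean equal to the noise-free
        expectation: the block average over a uniform layer agrees within 3 SE."""
        _, light = dark_light
        vol = simulate_volume(light, small_params)
        exp = expected_volume(light, small_params)
        rows = _choroid_rows(light, small_params)
        block = vol.intensity[:, :, rows]
        mu = exp.intensity[:, :, rows].mean()
        n = block.size
        se = mu / np.sqrt(n)  # exponential: SD = mean
        assert abs(block.mean() - mu) < 3 * se

    def test_fully_developed_speckle_contrast(self, dark_light, small_params):
        _, light = dark_light
        vol = simulate_volume(light, small_params)
        block = vol.intensity[:, :, _choroid_rows(light, small_params)]
        assert block.std() / block.mean() == pytest.approx(1.0, abs=0.05)

    def test_repeat_scans_share_scatterers_but_not_jitter(self, dark_light):
        _, light = dark_light
        params = ScanParams(n_x=64, n_y=8, n_z=256, jitter_sd=0.3, noise_floor=0.0, seed=1)
        v1 = simulate_volume(light, params, acquisition=1)
        v2 = simulate_volume(light, params, acquisition=2)
        assert not np.array_equal(v1.intensity, v2.intensity)
        a, b = v1.intensity.ravel(), v2.intensity.ravel()
        assert np.corrcoef(a, b)[0, 1] > 0.8


class TestSpectra:
    def test_zero_path_reflector_scales_envelope(self, source):
        spec = spectra_from_reflectors([(0.0, 0.04)], source, dc=1.0)
        expected = source.envelope(source.wavelength_grid()) * (1.0 + 2.0 * np.sqrt(0.04))
        np.testing.assert_allclose(spec, expected, rtol=1e-9)

    def test_out_of_range_reflector_warns(self, source):
        with pytest.warns(UserWarning, match="imaging range"):
            spectra_from_reflectors([(max_depth_um(source) + 100.0, 0.04)], source)

    def test_volume_spectra_roundtrip_to_boundary_peaks(self, source):
        """Spectra synthesized from the phantom reconstruct with peaks at the
        layer-boundary depths of the expected A-line."""
        params = ScanParams(n_x=4, n_y=2, n_z=256)
        ph = build_phantom({"map_shape": (2, 4), "curvature_um": 0.0})
        ph = apply_adaptation(ph, AdaptationState("dark"))
        spectra = synthesize_spectra(ph, params, source)
        calib = CalibrationProfile.from_source(source)
        prof = reconstruct_aline(spectra[0, 0], calib)
        refl = phantom_reflectors(ph, 4.875, 9.75, source.center)
        # strongest boundary: the hyper-reflective IS/OS (OS top)
        z_isos = ph.isos_depth_um()[0, 0]
        assert any(abs(z - z_isos) < 1e-6 for z, _ in refl)
        search = prof[2:]
        peak_um = (np.argmax(search) + 2) * calib.z_pitch_um
        assert abs(peak_um - z_isos) <= calib.z_pitch_um
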