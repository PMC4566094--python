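import numpy as np
import pytest

from rhodoct import (
    AdaptationState,
    ScanParams,
    SourceSpectrum,
    apply_adaptation,
    build_phantom,
)


@pytest.fixture
def small_params():
    """Compact scan geometry for fast unit tests."""
    return ScanParams(n_x=64, n_y=8, n_z=256, jitter_sd=0.0, noise_floor=0.0, seed=1)


@pytest.fixture
def small_phantom(small_params):
    """Flat, disc-free albino phantom matching ``small_params``."""
    return build_phantom(
        {"map_shape": (small_params.n_y, small_params.n_x), "curvature_um": 0.0}
    )


@pytest.fixture
def dark_light(small_phantom):
    dark = apply_adaptation(small_phantom, AdaptationState("dark"))
    light = apply_adaptation(small_phantom, AdaptationState("light"))
    return dark, light


@pytest.fixture
def source():
    return SourceSpectrum()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def delta_od_520(phantom) -> float:
    """Dark-minus-bleached single-pass OD at the 520 nm probe."""
    sp = phantom.spectrum
    return phantom.rhodopsin_od_peak * (sp.shape_dark(520.0) - sp.shape_bleached(520.0))
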