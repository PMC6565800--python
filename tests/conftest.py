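import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mfbia import GeneratorConfig, calibrate_generator, load_reference
from mfbia.cole import ColeParameters
from mfbia.simulate import render_spectrum
from mfbia.spectra import SpectrumMeta

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def calibration(reference):
    return calibrate_generator(reference)


@pytest.fixture(scope="session")
def men_biceps_params():
    """Cole state at the men-biceps normative means (alpha from calibration)."""
    return ColeParameters(r0=114.0, rinf=63.0, fc=42.3, alpha=0.8)


def make_spectrum(params, noise=0.0, seed=0, n_frequencies=256, f_min=4.0, f_max=1000.0, meta=None):
    """Render a synthetic spectrum from known Cole parameters."""
    cfg = GeneratorConfig(
        noise_sd_fraction=noise, n_frequencies=n_frequencies, f_min=f_min, f_max=f_max
    )
    rng = np.random.default_rng(seed)
    return render_spectrum(params, cfg, rng, meta or SpectrumMeta())


@pytest.fixture
def spectrum_factory():
    return make_spectrum
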