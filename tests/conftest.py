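import numpy as np
import pytest

from halofit.fixtures import FixtureSpec, generate_ideal_peak


@pytest.fixture(scope="session")
def default_spec() -> FixtureSpec:
    return FixtureSpec(seed=1)


@pytest.fixture(scope="session")
def ideal_peaks(default_spec):
    """The 42-peak seeded study used across the validation tests."""
    return [generate_ideal_peak(default_spec, i) for i in range(default_spec.n_peaks)]


@pytest.fixture
def noiseless_lorentzian():
    """A clean Lorentzian chromatogram: apex 100 grey, FWHM 60, background 50."""
    from halofit.image import Chromatogram
    from halofit.models import PeakParams, eval_peak

    n = 601
    x = np.arange(n, dtype=float)
    params = PeakParams("lorentzian", A=100.0 * np.pi * 60 / 2, alpha=300.0, width=60.0)
    y = np.asarray(eval_peak(params, x)) + 50.0
    return Chromatogram(positions=x, intensities=y), params
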