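import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from spadflim import (
    DetectorConfig,
    FluorophoreModel,
    Histogram,
    LaserPulseModel,
    NoiseModel,
    SimParams,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20240517)


@pytest.fixture
def pulse():
    return LaserPulseModel(fwhm_ns=1.25, turnoff_ns=0.5)


@pytest.fixture
def fluor():
    return FluorophoreModel(tau0_ns=5.0)


@pytest.fixture
def delta_pulse():
    """Nearly instantaneous excitation: arrival times ~ Exp(tau0)."""
    return LaserPulseModel(fwhm_ns=0.0, turnoff_ns=1e-9)


@pytest.fixture
def default_params():
    return SimParams()


def make_exponential_histogram(
    i0: float = 1000.0,
    tau: float = 5.0,
    tres: float = 0.3125,
    tw: float = 35.0,
) -> Histogram:
    """Noiseless synthetic histogram with counts i0*exp(-t/tau) at centers."""
    n_bins = int(round(tw / tres))
    centers = (np.arange(n_bins) + 0.5) * tres
    counts = np.round(i0 * np.exp(-centers / tau)).astype(int)
    return Histogram(counts=counts, tres_ns=tres, tw_ns=tw)


def numeric_convolution_cdf(pulse, fluor, t_max=200.0, dt=0.002):
    """Independent arrival-time cdf by brute-force grid convolution.

    Convolves Uniform(0, fwhm), Exp(turnoff) and Exp(tau0) densities on a
    fine regular grid; used as the oracle against both sampled times and
    the package's closed-form distribution functions.
    """
    grid = np.arange(0.0, t_max, dt)
    if pulse.fwhm_ns > 0:
        f = np.where(grid < pulse.fwhm_ns, 1.0 / pulse.fwhm_ns, 0.0)
    else:
        f = np.zeros_like(grid)
        f[0] = 1.0 / dt
    for scale in (pulse.turnoff_ns, fluor.tau0_ns):
        g = np.exp(-grid / scale) / scale
        f = np.convolve(f, g)[: grid.size] * dt
    cdf = np.cumsum(f) * dt
    cdf /= cdf[-1]
    return grid, cdf


@pytest.fixture
def small_detector():
    return DetectorConfig(n_pixel=1, tres_ns=0.3125, tw_ns=35.0, nw=2000)


@pytest.fixture
def quiet():
    return NoiseModel(0.0)
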