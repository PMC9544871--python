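import numpy as np
import pytest

from f3flim import AnalysisWindow, SimConfig, irf_moment, simulate_irf


@pytest.fixture(scope="session")
def cfg_ap5() -> SimConfig:
    """Typical TCSPC acquisition with 5% after-pulsing background."""
    return SimConfig(afterpulsing=0.05, seed=1234)


@pytest.fixture(scope="session")
def cfg_clean() -> SimConfig:
    """Same acquisition without background."""
    return SimConfig(afterpulsing=0.0, seed=1234)


@pytest.fixture(scope="session")
def irf_hist(cfg_clean):
    """A well-sampled measured IRF (10^6 photons)."""
    return simulate_irf(cfg_clean, 10**6, seed=99)


@pytest.fixture(scope="session")
def tau_irf(irf_hist) -> float:
    return irf_moment(irf_hist)


@pytest.fixture(scope="session")
def full_window(cfg_clean) -> AnalysisWindow:
    return AnalysisWindow(cfg_clean.acq_window)


def binned_exponential(tau: float, bin_width: float, n_bins: int, t_shift: float = 0.0,
                       total: float = 1.0) -> np.ndarray:
    """Noiseless exponential decay integrated over the histogram bins.

    Used as an analytic fixture: exact bin contents of total*exp(-(t-t_shift)/tau)
    for t >= t_shift, no noise, no wrap-around.
    """
    edges = bin_width * np.arange(n_bins + 1) - t_shift
    edges = np.clip(edges, 0.0, None)
    cdf = 1.0 - np.exp(-edges / tau)
    return total * np.diff(cdf)
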