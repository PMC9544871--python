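"""Core containers for TCSPC decay data, instrument response and calibration.

Conventions used throughout the package:

* Time is in nanoseconds.  The acquisition axis starts at t = 0 and spans the
  acquisition window ``T``; histogram bins are half-open intervals
  ``[k*delta, (k+1)*delta)`` with ``delta = T / n_bins``.
* A FLIM cube is indexed ``(bin, row, col)``; on disk it is a multi-page
  16-bit TIFF, one page per time bin in increasing time order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np


class ConfigError(ValueError):
    """A simulator or analysis configuration violates its invariants."""


class DataError(ValueError):
    """Input data violate a structural contract (shape, range, format)."""


@dataclass(frozen=True)
class SimConfig:
    """Acquisition and noise parameters for the Monte-Carlo TCSPC simulator.

    Parameters
    ----------
    acq_window : float
        Acquisition (measurement) window ``T`` in ns.
    n_bins : int
        Number of uniform time bins; bin width is ``acq_window / n_bins``.
    irf_centre : float
        Centre ``t0`` of the Gaussian instrument response, ns.
    irf_sigma : float
        Standard deviation of the Gaussian instrument response, ns.
    rep_rate : float
        Laser repetition rate in MHz.  The inter-pulse period is
        ``1000 / rep_rate`` ns; photon arrival times are wrapped modulo this
        period and times landing beyond the acquisition window are discarded.
    afterpulsing : float
        Background fraction ``Ap``; ``round(Ap * N)`` uniformly distributed
        background photons are added to a decay of ``N`` signal photons.
    seed : int
        Seed for the pseudo-random number generator.
    """

    acq_window: float = 25.0
    n_bins: int = 256
    irf_centre: float = 3.2
    irf_sigma: float = 0.15
    rep_rate: float = 20.0
    afterpulsing: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ConfigError("n_bins must be at least 2")
        if self.acq_window <= 0:
            raise ConfigError("acq_window must be positive")
        if self.afterpulsing < 0:
            raise ConfigError("afterpulsing must be non-negative")
        if self.irf_sigma < 0:
            raise ConfigError("irf_sigma must be non-negative")
        if self.rep_rate <= 0:
            raise ConfigError("rep_rate must be positive")
        if self.period < self.bin_width:
            raise ConfigError("laser period must be at least one bin width")

    @property
    def bin_width(self) -> float:
        return self.acq_window / self.n_bins

    @property
    def period(self) -> float:
        """Inter-pulse period in ns."""
        return 1000.0 / self.rep_rate

    def replace(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass
class DecayHistogram:
    """Photon counts over uniform time bins for a single decay."""

    counts: np.ndarray
    bin_width: float
    t_start: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise DataError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise DataError("counts must be non-negative")
        if self.bin_width <= 0:
            raise DataError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_edges(self) -> np.ndarray:
        return self.t_start + self.bin_width * np.arange(self.n_bins + 1)


@dataclass
class IRFModel:
    """Instrument response, as Gaussian parameters and/or a measured histogram.

    Either ``histogram`` or the Gaussian pair ``(centre, sigma)`` must be
    given.  The centre-of-mass moment used in the analysis chain is taken
    from the histogram when available, otherwise from the Gaussian
    parameters (mean + half a bin, matching the discrete estimator's
    mid-bin convention).
    """

    centre: Optional[float] = None
    sigma: Optional[float] = None
    histogram: Optional[DecayHistogram] = None

    def __post_init__(self) -> None:
        if self.histogram is None and self.centre is None:
            raise ConfigError("IRFModel needs a histogram or Gaussian parameters")
        if self.sigma is not None and self.sigma < 0:
            raise ConfigError("IRF sigma must be non-negative")

    def moment(self, bin_width: Optional[float] = None) -> float:
        """Centre-of-mass of the IRF on the acquisition axis (ns).

        For a smooth IRF the discrete mid-bin moment equals the true mean,
        so the parametric value is the centre itself; a zero-width IRF
        snaps to the midpoint of its containing bin, matching what the
        discrete estimator reports for the equivalent histogram.
        """
        if self.histogram is not None:
            from .cmm import irf_moment

            return irf_moment(self.histogram)
        if self.sigma and self.sigma > 0:
            return float(self.centre)
        if bin_width is None:
            raise ConfigError("bin_width required for a delta-IRF moment")
        return (np.floor(self.centre / bin_width) + 0.5) * bin_width

    def binned(self, n_bins: int, bin_width: float) -> np.ndarray:
        """IRF as a normalized histogram on the analysis grid."""
        if self.histogram is not None:
            h = self.histogram.counts.astype(float)
            s = h.sum()
            if s <= 0:
                raise DataError("measured IRF histogram is empty")
            return h / s
        from scipy.special import erf

        edges = bin_width * np.arange(n_bins + 1)
        if self.sigma and self.sigma > 0:
            z = (edges - self.centre) / (self.sigma * np.sqrt(2.0))
            cdf = 0.5 * (1.0 + erf(z))
            p = np.diff(cdf)
        else:
            p = np.zeros(n_bins)
            k = min(int(self.centre // bin_width), n_bins - 1)
            p[k] = 1.0
        s = p.sum()
        if s <= 0:
            raise DataError("parametric IRF has no mass inside the window")
        return p / s


@dataclass
class FLIMStack:
    """A 3-D FLIM cube of per-pixel decay histograms plus metadata.

    ``cube`` is indexed ``(bin, row, col)``.  Ground-truth maps are attached
    when the stack comes from the simulator.
    """

    cube: np.ndarray
    acq_window: float
    rep_rate: float = 20.0
    seed: Optional[int] = None
    afterpulsing: float = 0.0
    lifetime_map: Optional[np.ndarray] = None
    photon_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.cube = np.asarray(self.cube)
        if self.cube.ndim != 3:
            raise DataError("cube must be (bin, row, col)")
        if np.any(self.cube < 0):
            raise DataError("cube counts must be non-negative")

    @property
    def n_bins(self) -> int:
        return self.cube.shape[0]

    @property
    def shape(self) -> tuple:
        return self.cube.shape[1:]

    @property
    def bin_width(self) -> float:
        return self.acq_window / self.n_bins

    def pixel(self, row: int, col: int) -> DecayHistogram:
        return DecayHistogram(self.cube[:, row, col], self.bin_width)


@dataclass(frozen=True)
class AnalysisWindow:
    """Centre-of-mass analysis window ``[0, length]`` on the acquisition axis.

    ``effective(tau_irf)`` is the window length seen by the decay itself,
    i.e. the total length minus the IRF centre-of-mass.
    """

    length: float

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ConfigError("analysis window length must be positive")

    def effective(self, tau_irf: float) -> float:
        eff = self.length - tau_irf
        if eff <= 0:
            raise ConfigError(
                f"effective window {self.length} - {tau_irf:.3f} ns is not positive"
            )
        return eff

    def n_window_bins(self, bin_width: float) -> int:
        """Number of bins whose left edge lies inside the window."""
        return int(np.ceil(self.length / bin_width - 1e-12))


@dataclass
class LifetimeMap:
    """Per-pixel lifetime estimates with validity mask and intensity."""

    tau: np.ndarray
    intensity: np.ndarray
    valid: np.ndarray
    window: Optional[AnalysisWindow] = None
    method: str = ""

    def __post_init__(self) -> None:
        self.tau = np.asarray(self.tau, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if not (self.tau.shape == self.intensity.shape == self.valid.shape):
            raise DataError("tau, intensity and valid must share a shape")


@dataclass
class CalibrationParams:
    """Rational-model coefficients and fusion parameters for F3-CMM.

    The photon-efficiency curve F'(alpha) = A*alpha + B + C/alpha, with
    alpha the ratio of lifetime to *effective* analysis-window length,
    determines the lifetime cut-off between two windows i and j as
    ``tau_c = sqrt(Ta_i * Ta_j * C / A)``.
    """

    A: float = 3.218
    B: float = 0.0
    C: float = 0.07339
    b: float = 20.0
    windows: tuple = (25.0, 12.5, 6.25)
    r_squared: Optional[float] = None
    n_repeats: Optional[int] = None
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.A <= 0 or self.C <= 0:
            raise ConfigError("A and C must be positive")
        if self.b <= 0:
            raise ConfigError("blending factor b must be positive")
        w = tuple(float(x) for x in self.windows)
        if len(w) != 3 or not (w[0] > w[1] > w[2] > 0):
            raise ConfigError("windows must be three decreasing positive lengths")
        self.windows = w

    def analysis_windows(self) -> tuple:
        return tuple(AnalysisWindow(w) for w in self.windows)

    def cutoffs(self, tau_irf: float) -> tuple:
        """(tau_c12, tau_c23) for the given IRF moment."""
        from .f3cmm import cutoff

        w1, w2, w3 = self.analysis_windows()
        return (
            cutoff(w1.effective(tau_irf), w2.effective(tau_irf), self.A, self.C),
            cutoff(w2.effective(tau_irf), w3.effective(tau_irf), self.A, self.C),
        )


@dataclass
class MetricsResult:
    """Repeated-measurement summary for one simulated condition."""

    tau_true: float
    n_photons: int
    n_repeats: int
    tau_mean: float
    delta_tau: float
    sigma_tau: float
    f_value: float
    f_prime: float
    n_failed: int = 0
    flagged: bool = False
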