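"""Single-exponential least-squares decay fitting (the conventional baseline).

The model is the binned IRF convolved with a complete single-exponential
decay, scaled by an amplitude and offset by a constant background:

    model(t; tau, A, c) = A * (IRF (*) exp(-t/tau))_bin + c

fitted by unweighted least squares on the acquisition grid.  Incomplete
decays (tails re-excited by the next laser pulse) are outside this model.
"""

from __future__ import annotations

from typing import Union

import numpy as np
from scipy.optimize import least_squares

from . import cmm as _cmm
from .datatypes import (
    AnalysisWindow,
    ConfigError,
    DataError,
    DecayHistogram,
    FLIMStack,
    IRFModel,
    LifetimeMap,
)

__all__ = ["decay_model", "lsm_fit", "lsm_batch", "lsm_stack", "batch_estimator"]


def _binned_irf(irf, n_bins: int, bin_width: float) -> np.ndarray:
    if isinstance(irf, IRFModel):
        return irf.binned(n_bins, bin_width)
    if isinstance(irf, DecayHistogram):
        h = irf.counts.astype(float)
        s = h.sum()
        if s <= 0:
            raise DataError("IRF histogram is empty")
        return h / s
    raise ConfigError("irf must be an IRFModel or DecayHistogram")


def decay_model(tau: float, irf_binned: np.ndarray, bin_width: float) -> np.ndarray:
    """Unit-amplitude model decay: discrete IRF (*) exponential, on the grid."""
    n_bins = irf_binned.shape[0]
    t_mid = bin_width * (np.arange(n_bins) + 0.5)
    kernel = np.exp(-t_mid / tau)
    full = np.convolve(irf_binned, kernel)[:n_bins]
    return full


def lsm_fit(
    hist: DecayHistogram,
    irf,
    window: AnalysisWindow = None,
    n_pre_bins: int = _cmm.DEFAULT_PRE_BINS,
):
    """Fit (tau, amplitude, background) to one decay histogram.

    Starting values: tau from the CMM estimate (falling back to a quarter
    of the window), amplitude from the peak count, background from the
    pre-rise mean.  Returns ``(tau, amplitude, background)``; a fit that
    fails to converge returns NaNs rather than raising.
    """
    counts = hist.counts.astype(float)
    n_bins = hist.n_bins
    bin_width = hist.bin_width
    if window is None:
        window = AnalysisWindow(bin_width * n_bins)
    n_win = min(window.n_window_bins(bin_width), n_bins)
    if np.count_nonzero(counts[:n_win]) < 4:
        return float("nan"), float("nan"), float("nan")
    irf_binned = _binned_irf(irf, n_bins, bin_width)

    tau_irf = (
        irf.moment(bin_width)
        if isinstance(irf, IRFModel)
        else _cmm.irf_moment(irf)
    )
    tau0 = _cmm.cmm_pixel(hist, tau_irf, window, n_pre_bins=n_pre_bins)
    if not np.isfinite(tau0) or tau0 <= 0:
        tau0 = 0.25 * window.length
    _, bg0 = _cmm.subtract_background(counts, n_pre_bins)
    amp0 = max(counts.max() - bg0, 1.0)

    y = counts[:n_win]

    def residuals(p):
        log_tau, amp, bg = p
        model = amp * decay_model(np.exp(log_tau), irf_binned, bin_width)[:n_win] + bg
        return model - y

    try:
        sol = least_squares(
            residuals,
            x0=[np.log(tau0), amp0 / max(decay_model(tau0, irf_binned, bin_width).max(), 1e-12), bg0],
            method="lm",
            max_nfev=400,
        )
    except Exception:
        return float("nan"), float("nan"), float("nan")
    if not sol.success and sol.status <= 0:
        return float("nan"), float("nan"), float("nan")
    tau = float(np.exp(sol.x[0]))
    return tau, float(sol.x[1]), float(sol.x[2])


def lsm_batch(
    counts,
    irf,
    window: AnalysisWindow,
    bin_width: float,
    n_pre_bins: int = _cmm.DEFAULT_PRE_BINS,
) -> np.ndarray:
    """Per-row least-squares lifetimes for a (rows, n_bins) batch."""
    counts = np.asarray(counts)
    out = np.empty(counts.shape[0])
    for i, row in enumerate(counts):
        out[i] = lsm_fit(DecayHistogram(np.maximum(row, 0), bin_width), irf, window, n_pre_bins)[0]
    return out


def lsm_stack(
    stack: FLIMStack,
    irf,
    window: AnalysisWindow = None,
    n_pre_bins: int = _cmm.DEFAULT_PRE_BINS,
) -> LifetimeMap:
    """Per-pixel least-squares fit over a FLIM stack; failed pixels masked."""
    if window is None:
        window = AnalysisWindow(stack.acq_window)
    flat = stack.cube.reshape(stack.n_bins, -1).T
    taus = lsm_batch(flat, irf, window, stack.bin_width, n_pre_bins)
    tau_map = taus.reshape(stack.shape)
    return LifetimeMap(
        tau=tau_map,
        intensity=stack.cube.sum(axis=0).astype(float),
        valid=np.isfinite(tau_map),
        window=window,
        method="lsm",
    )


def batch_estimator(irf, window: AnalysisWindow, bin_width: float, **kwargs):
    """A ``counts -> lifetimes`` callable for the benchmark harness."""

    def estimate(counts: np.ndarray) -> np.ndarray:
        return lsm_batch(counts, irf, window, bin_width, **kwargs)

    return estimate
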