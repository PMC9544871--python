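"""F3-CMM: three-window centre-of-mass lifetime fusion.

A single centre-of-mass analysis window cannot serve all lifetimes: a wide
window accumulates background noise under short decays, while a narrow
window truncates (and thus biases) long decays.  F3-CMM runs CMM at three
nested analysis windows (by default 25, 12.5 and 6.25 ns — binary
subdivisions of the acquisition window, all anchored at t = 0) and blends
the three estimates per pixel with lifetime-dependent logistic weights:

    tau_F3 = W12*tau_T1 + (W23 - W12)*tau_T2 + (1 - W23)*tau_T3
    Wij(tau) = 1 / (1 + exp(-b * (tau - tau_c_ij) / tau_c_ij))

The cut-off lifetimes tau_c_ij come from the empirical photon-efficiency
curve F'(alpha) = A*alpha + B + C/alpha, with alpha the ratio of lifetime
to effective window length: two windows perform equally well at
tau_c = sqrt(Ta_i * Ta_j * C / A).  Because the true lifetime is unknown,
the weights are evaluated at the mid-window (T2) CMM estimate, which is
accurate and precise around both cut-offs.

``calibrate`` re-derives A, B, C from a simulation study; shipped defaults
are A = 3.218, C = 0.07339 and blending factor b = 20.
"""

from __future__ import annotations

from typing import Optional, Union

import numpy as np

from . import cmm as _cmm
from .datatypes import (
    AnalysisWindow,
    CalibrationParams,
    ConfigError,
    FLIMStack,
    LifetimeMap,
    SimConfig,
)
from .metrics import benchmark, results_frame

__all__ = [
    "cutoff",
    "weight",
    "fuse",
    "pilot_weights",
    "f3cmm_batch",
    "f3cmm_stack",
    "calibrate",
    "fit_rational",
    "batch_estimator",
]

#: clamp on the logistic exponent; exp(±700) is the float64 overflow edge
_EXP_CLAMP = 700.0


def cutoff(ta_i: float, ta_j: float, A: float, C: float) -> float:
    """Lifetime cut-off between two analysis windows, sqrt(Ta_i*Ta_j*C/A)."""
    if ta_i <= 0 or ta_j <= 0:
        raise ConfigError("effective window lengths must be positive")
    if A <= 0 or C <= 0:
        raise ConfigError("A and C must be positive")
    return float(np.sqrt(ta_i * ta_j * C / A))


def weight(tau, tau_c: float, b: float):
    """Logistic blending weight ``1 / (1 + exp(-b*(tau - tau_c)/tau_c))``.

    Saturates to 0/1 rather than overflowing; NaN lifetimes give NaN.
    """
    if tau_c <= 0:
        raise ConfigError("tau_c must be positive")
    tau = np.asarray(tau, dtype=float)
    z = -b * (tau - tau_c) / tau_c
    w = 1.0 / (1.0 + np.exp(np.clip(z, -_EXP_CLAMP, _EXP_CLAMP)))
    w = np.where(z >= _EXP_CLAMP, 0.0, np.where(z <= -_EXP_CLAMP, 1.0, w))
    return float(w) if w.ndim == 0 else w


def fuse(tau1, tau2, tau3, w12, w23):
    """Blend the three window estimates; the coefficients sum to one.

    A window whose coefficient is exactly zero does not contribute, even
    if its own estimate is invalid (NaN) — e.g. a long decay that the
    narrowest window cannot invert is still fused from the wider windows.
    """
    c1 = np.asarray(w12, dtype=float)
    c2 = np.asarray(w23, dtype=float) - c1
    c3 = 1.0 - np.asarray(w23, dtype=float)
    terms = []
    for c, t in ((c1, tau1), (c2, tau2), (c3, tau3)):
        t = np.asarray(t, dtype=float)
        terms.append(np.where(c == 0.0, 0.0, c * t))
    out = terms[0] + terms[1] + terms[2]
    return float(out) if np.ndim(out) == 0 else out


def pilot_weights(
    tau_mid,
    calibration: CalibrationParams,
    tau_irf: float,
    tau_wide=None,
):
    """Blending weights evaluated at the mid-window lifetime estimate.

    The true lifetime is unknown, so the weights use the T2-window CMM
    estimate as a pilot.  Where that estimate is invalid but a wide-window
    (T1) estimate is supplied and valid, the latter substitutes; pixels
    with no valid pilot get NaN weights.
    """
    tau_c12, tau_c23 = calibration.cutoffs(tau_irf)
    pilot = np.asarray(tau_mid, dtype=float)
    if tau_wide is not None:
        tau_wide = np.asarray(tau_wide, dtype=float)
        pilot = np.where(np.isfinite(pilot), pilot, tau_wide)
    w12 = weight(pilot, tau_c12, calibration.b)
    w23 = weight(pilot, tau_c23, calibration.b)
    return w12, w23


def f3cmm_batch(
    counts,
    irf,
    calibration: CalibrationParams,
    bin_width: float,
    n_pre_bins: int = _cmm.DEFAULT_PRE_BINS,
    n_iter: int = _cmm.DEFAULT_ITERATIONS,
    background: Union[str, float] = "shared",
) -> np.ndarray:
    """Fused F3-CMM lifetimes for a (rows, n_bins) batch of decays."""
    counts = np.asarray(counts, dtype=float)
    tau_irf = _cmm._irf_moment_of(irf, bin_width)
    w1, w2, w3 = calibration.analysis_windows()
    taus = [
        _cmm.cmm_batch(
            counts,
            tau_irf,
            w,
            bin_width,
            n_pre_bins=n_pre_bins,
            n_iter=n_iter,
            background=background,
        )
        for w in (w1, w2, w3)
    ]
    w12, w23 = pilot_weights(taus[1], calibration, tau_irf, tau_wide=taus[0])
    return fuse(taus[0], taus[1], taus[2], w12, w23)


def f3cmm_stack(
    stack: FLIMStack,
    irf,
    calibration: Optional[CalibrationParams] = None,
    n_pre_bins: int = _cmm.DEFAULT_PRE_BINS,
    n_iter: int = _cmm.DEFAULT_ITERATIONS,
    background: Union[str, float] = "pixel",
) -> LifetimeMap:
    """Apply F3-CMM to every pixel of a FLIM stack."""
    if calibration is None:
        calibration = CalibrationParams()
    if stack.acq_window < calibration.windows[0]:
        raise ConfigError(
            "stack acquisition window does not cover the widest analysis window"
        )
    flat = stack.cube.reshape(stack.n_bins, -1).T.astype(float)
    taus = f3cmm_batch(
        flat,
        irf,
        calibration,
        stack.bin_width,
        n_pre_bins=n_pre_bins,
        n_iter=n_iter,
        background=background,
    )
    tau_map = taus.reshape(stack.shape)
    return LifetimeMap(
        tau=tau_map,
        intensity=stack.cube.sum(axis=0).astype(float),
        valid=np.isfinite(tau_map),
        method="f3cmm",
    )


def batch_estimator(irf, calibration: CalibrationParams, bin_width: float, **kwargs):
    """A ``counts -> lifetimes`` callable for the benchmark harness."""

    def estimate(counts: np.ndarray) -> np.ndarray:
        return f3cmm_batch(counts, irf, calibration, bin_width, **kwargs)

    return estimate


def fit_rational(alpha, f_prime_values):
    """Unweighted least-squares fit of F'(alpha) = A*alpha + B + C/alpha.

    Linear in (A, B, C); returns ``(A, B, C), r_squared``.
    """
    alpha = np.asarray(alpha, dtype=float)
    y = np.asarray(f_prime_values, dtype=float)
    good = np.isfinite(alpha) & np.isfinite(y) & (alpha > 0)
    alpha, y = alpha[good], y[good]
    if alpha.size < 4:
        raise ConfigError("too few points for the rational fit")
    design = np.column_stack([alpha, np.ones_like(alpha), 1.0 / alpha])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    ss_tot = ((y - y.mean()) ** 2).sum()
    if ss_tot <= 0:
        raise ConfigError("degenerate calibration data")
    r2 = 1.0 - (resid**2).sum() / ss_tot
    if coef[0] <= 0 or coef[2] <= 0:
        raise ConfigError(
            f"rational fit returned non-positive A or C: A={coef[0]:.4g}, C={coef[2]:.4g}"
        )
    return (float(coef[0]), float(coef[1]), float(coef[2])), float(r2)


def calibrate(
    cfg: Optional[SimConfig] = None,
    windows: tuple = (25.0, 12.5, 6.25),
    n_photons: int = 5000,
    n_repeats: int = 1024,
    tau_grid=None,
    alpha_max: float = 0.7,
    b: float = 20.0,
    seed: int = 0,
    return_table: bool = False,
):
    """Derive the rational-model coefficients from a simulation study.

    CMM is benchmarked at the three analysis windows over a common
    lifetime grid (default 0.25-4.5 ns in 0.25 ns steps); the per-point
    F'-values, expressed against alpha = lifetime / effective window
    length, collapse onto a single curve that is fitted with
    ``fit_rational``.  The fit uses the pooled points with
    ``alpha <= alpha_max``; beyond that only the narrowest window
    contributes and its finite-window amplification departs from the
    rational form.  The finite-window correction is run to convergence
    (1 ps tolerance) here so that the long-lifetime points carry no
    iteration-truncation bias.
    """
    if cfg is None:
        cfg = SimConfig(afterpulsing=0.05, seed=seed)
    if tau_grid is None:
        tau_grid = np.arange(0.25, 4.51, 0.25)
    tau_grid = np.asarray(tau_grid, dtype=float)

    from .tcspc_sim import simulate_irf

    irf_seed, *window_seeds = np.random.SeedSequence(seed).spawn(1 + len(windows))
    irf_hist = simulate_irf(cfg, 10**6, seed=irf_seed)
    tau_irf = _cmm.irf_moment(irf_hist)

    rows = []
    for k, w_len in enumerate(windows):
        window = AnalysisWindow(float(w_len))
        eff = window.effective(tau_irf)
        estimator = _cmm.batch_estimator(
            tau_irf,
            window,
            cfg.bin_width,
            background="shared",
            tol=1e-3,
        )
        results = benchmark(
            estimator,
            cfg,
            tau_grid,
            n_photons,
            n_repeats,
            seed=window_seeds[k],
        )
        frame = results_frame(results)
        frame["window"] = w_len
        frame["alpha"] = frame["tau_true"] / eff
        rows.append(frame)

    import pandas as pd

    table = pd.concat(rows, ignore_index=True)
    mask = (table["alpha"] <= alpha_max) & ~table["flagged"]
    (A, B, C), r2 = fit_rational(
        table.loc[mask, "alpha"], table.loc[mask, "Fprime"]
    )
    params = CalibrationParams(
        A=A,
        B=B,
        C=C,
        b=b,
        windows=tuple(float(w) for w in windows),
        r_squared=r2,
        n_repeats=n_repeats,
        seed=seed,
    )
    if return_table:
        return params, table
    return params
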