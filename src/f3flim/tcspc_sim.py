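"""Monte-Carlo simulation of TCSPC decays and FLIM image stacks.

Photon arrival times are the sum of an exponential emission delay and a
Gaussian excitation (IRF) time, both drawn by inverse-transform sampling.
Arrival times are wrapped modulo the inter-pulse laser period; times that
still fall beyond the acquisition window are not recorded.  Detector
after-pulsing is modelled as ``round(Ap * N)`` extra photons distributed
uniformly over the acquisition window.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .datatypes import ConfigError, DecayHistogram, FLIMStack, SimConfig

__all__ = [
    "sample_emission_times",
    "sample_excitation_times",
    "simulate_decay",
    "simulate_decays",
    "simulate_irf",
    "simulate_stack",
    "n_background",
]


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def n_background(n_photons: int, afterpulsing: float) -> int:
    """Number of background photons, ``round(Ap * N)`` with half-up rounding."""
    return int(np.floor(afterpulsing * n_photons + 0.5))


def sample_emission_times(n: int, tau: float, seed=None) -> np.ndarray:
    """Draw ``n`` exponential emission delays with mean lifetime ``tau`` (ns).

    Inverse-transform sampling of the emission CPDF 1 - exp(-t/tau).
    """
    if tau <= 0:
        raise ConfigError("lifetime tau must be positive")
    if n < 0:
        raise ConfigError("photon count must be non-negative")
    u = _rng(seed).random(n)
    return -tau * np.log1p(-u)


def sample_excitation_times(n: int, t0: float, sigma: float, seed=None) -> np.ndarray:
    """Draw ``n`` Gaussian excitation times centred at ``t0`` with std ``sigma``."""
    if sigma < 0:
        raise ConfigError("IRF sigma must be non-negative")
    if n < 0:
        raise ConfigError("photon count must be non-negative")
    if sigma == 0:
        return np.full(n, float(t0))
    return _rng(seed).normal(t0, sigma, n)


def _histogram_rows(times: np.ndarray, keep: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Bin per-row arrival times into (rows, n_bins) count matrices."""
    n_rows = times.shape[0]
    idx = np.minimum((times / cfg.bin_width).astype(np.int64), cfg.n_bins - 1)
    rows = np.repeat(np.arange(n_rows), times.shape[1])
    flat = (rows * cfg.n_bins + idx.ravel())[keep.ravel()]
    out = np.bincount(flat, minlength=n_rows * cfg.n_bins)
    return out.reshape(n_rows, cfg.n_bins)


def simulate_decays(
    cfg: SimConfig,
    tau: float,
    n_photons: int,
    n_repeats: int,
    rng=None,
    n_bkg: Optional[int] = None,
) -> np.ndarray:
    """Simulate ``n_repeats`` independent decays; returns (n_repeats, n_bins) counts.

    This is the vectorized core behind :func:`simulate_decay` and the
    repeated-measurement benchmark harness.  ``n_bkg`` overrides the
    ``round(Ap * N)`` background photon number (e.g. for background-only
    runs with no signal).
    """
    if n_photons < 0:
        raise ConfigError("photon count must be non-negative")
    gen = _rng(cfg.seed if rng is None else rng)
    if n_bkg is None:
        n_bkg = n_background(n_photons, cfg.afterpulsing)
    parts = []
    if n_photons > 0:
        if tau <= 0:
            raise ConfigError("lifetime tau must be positive")
        em = gen.exponential(tau, (n_repeats, n_photons))
        if cfg.irf_sigma > 0:
            em += gen.normal(cfg.irf_centre, cfg.irf_sigma, (n_repeats, n_photons))
        else:
            em += cfg.irf_centre
        parts.append(em % cfg.period)
    if n_bkg > 0:
        parts.append(gen.uniform(0.0, cfg.acq_window, (n_repeats, n_bkg)))
    if not parts:
        return np.zeros((n_repeats, cfg.n_bins), dtype=np.int64)
    times = np.concatenate(parts, axis=1)
    keep = times < cfg.acq_window
    return _histogram_rows(times, keep, cfg)


def simulate_decay(cfg: SimConfig, tau: float, n_photons: int, seed=None) -> DecayHistogram:
    """Simulate a single TCSPC decay histogram.

    ``n_photons`` signal photons with lifetime ``tau`` plus
    ``round(Ap * n_photons)`` uniform background photons.  When the laser
    period equals or is shorter than the acquisition window every photon is
    recorded and the histogram total is exactly signal + background;
    photons wrapped into ``[T, period)`` are discarded otherwise.
    """
    gen = _rng(cfg.seed if seed is None else seed)
    counts = simulate_decays(cfg, tau, n_photons, 1, rng=gen)[0]
    return DecayHistogram(counts, cfg.bin_width)


def simulate_irf(cfg: SimConfig, n_photons: int, seed=None) -> DecayHistogram:
    """Simulate a measured IRF by recording excitation times only."""
    if n_photons < 0:
        raise ConfigError("photon count must be non-negative")
    gen = _rng(cfg.seed if seed is None else seed)
    t = sample_excitation_times(n_photons, cfg.irf_centre, cfg.irf_sigma, gen)
    t = t % cfg.period
    keep = (t < cfg.acq_window)[None, :]
    counts = _histogram_rows(t[None, :], keep, cfg)[0]
    return DecayHistogram(counts, cfg.bin_width)


def pixel_seed_sequence(seed: int, row: int, col: int) -> np.random.SeedSequence:
    """Deterministic, decorrelated per-pixel seed derivation."""
    return np.random.SeedSequence(entropy=seed, spawn_key=(row, col))


def simulate_stack(
    cfg: SimConfig,
    lifetime_map: np.ndarray,
    photon_map: np.ndarray,
    seed: Optional[int] = None,
) -> FLIMStack:
    """Simulate a FLIM image stack from per-pixel lifetime and photon-count maps.

    Each pixel is an independent :func:`simulate_decay` run with a seed
    derived from ``(seed, row, col)``, so stacks are bit-reproducible and
    any sub-region can be regenerated in isolation.
    """
    lifetime_map = np.asarray(lifetime_map, dtype=float)
    photon_map = np.asarray(photon_map)
    if lifetime_map.shape != photon_map.shape:
        raise ConfigError("lifetime_map and photon_map must have the same shape")
    if lifetime_map.ndim != 2:
        raise ConfigError("maps must be two-dimensional")
    if np.any(lifetime_map <= 0):
        raise ConfigError("every lifetime must be positive")
    if np.any(photon_map < 0):
        raise ConfigError("every photon count must be non-negative")
    base_seed = cfg.seed if seed is None else seed
    n_rows, n_cols = lifetime_map.shape
    cube = np.zeros((cfg.n_bins, n_rows, n_cols), dtype=np.int64)
    for r in range(n_rows):
        for c in range(n_cols):
            gen = np.random.default_rng(pixel_seed_sequence(base_seed, r, c))
            counts = simulate_decays(
                cfg, float(lifetime_map[r, c]), int(photon_map[r, c]), 1, rng=gen
            )[0]
            cube[:, r, c] = counts
    return FLIMStack(
        cube=cube,
        acq_window=cfg.acq_window,
        rep_rate=cfg.rep_rate,
        seed=base_seed,
        afterpulsing=cfg.afterpulsing,
        lifetime_map=lifetime_map.copy(),
        photon_map=np.asarray(photon_map, dtype=float).copy(),
    )
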