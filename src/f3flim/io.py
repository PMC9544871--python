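"""Persistence: TIFF stacks with plain-text sidecars, lifetime maps, calibrations.

A FLIM stack is stored as a multi-page 16-bit TIFF (page k = time bin k,
increasing time) next to a YAML sidecar ``<stack>.yaml`` carrying the
acquisition metadata; simulated ground-truth maps go to 32-bit float
TIFFs referenced from the sidecar.  Lifetime maps are written as 32-bit
float TIFF plus a validity mask and a plain-text distribution summary.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

from .datatypes import (
    CalibrationParams,
    ConfigError,
    DataError,
    FLIMStack,
    LifetimeMap,
)

__all__ = [
    "write_stack",
    "read_stack",
    "write_lifetime_map",
    "read_lifetime_map",
    "gaussian_summary",
    "write_calibration",
    "read_calibration",
]

log = logging.getLogger("f3flim")

_REQUIRED_META = ("acq_window",)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".yaml")


def write_stack(stack: FLIMStack, path) -> Path:
    """Write a FLIM stack as multi-page 16-bit TIFF plus YAML sidecar.

    Counts above 65535 are an error (never silently clipped); the message
    names the first offending (bin, row, col).
    """
    path = Path(path)
    cube = np.asarray(stack.cube)
    if cube.max(initial=0) > 65535:
        b, r, c = np.argwhere(cube > 65535)[0]
        raise DataError(
            f"count {cube[b, r, c]} at (bin={b}, row={r}, col={c}) exceeds the "
            "16-bit TIFF range"
        )
    tifffile.imwrite(path, cube.astype(np.uint16), photometric="minisblack")
    meta = {
        "acq_window": float(stack.acq_window),
        "n_bins": int(stack.n_bins),
        "rep_rate": float(stack.rep_rate),
        "afterpulsing": float(stack.afterpulsing),
    }
    if stack.seed is not None:
        meta["seed"] = int(stack.seed)
    for name, arr in (("lifetime_map", stack.lifetime_map), ("photon_map", stack.photon_map)):
        if arr is not None:
            gt_path = path.with_name(path.stem + f"_{name}.tif")
            tifffile.imwrite(gt_path, np.asarray(arr, dtype=np.float32), photometric="minisblack")
            meta[name] = gt_path.name
    with open(_sidecar_path(path), "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=True)
    log.info("wrote stack %s (%d bins, %s pixels)", path, stack.n_bins, stack.shape)
    return path


def read_stack(
    path,
    acq_window: Optional[float] = None,
    rep_rate: Optional[float] = None,
    afterpulsing: Optional[float] = None,
) -> FLIMStack:
    """Read a FLIM stack TIFF; metadata from the sidecar, overridable by args.

    A foreign TIFF without a sidecar loads as long as ``acq_window`` is
    supplied; otherwise the error lists the missing keys.
    """
    path = Path(path)
    cube = tifffile.imread(path)
    if cube.ndim == 2:  # single-page TIFF: one time bin
        cube = cube[None, :, :]
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = yaml.safe_load(fh) or {}
    overrides = {
        "acq_window": acq_window,
        "rep_rate": rep_rate,
        "afterpulsing": afterpulsing,
    }
    for key, val in overrides.items():
        if val is not None:
            meta[key] = val
    missing = [k for k in _REQUIRED_META if meta.get(k) is None]
    if missing:
        raise DataError(
            f"stack {path} has no sidecar metadata; supply: {', '.join(missing)}"
        )
    gt = {}
    for name in ("lifetime_map", "photon_map"):
        ref = meta.get(name)
        if ref:
            gt_path = path.parent / ref
            if gt_path.exists():
                gt[name] = tifffile.imread(gt_path).astype(float)
    return FLIMStack(
        cube=cube.astype(np.int64),
        acq_window=float(meta["acq_window"]),
        rep_rate=float(meta.get("rep_rate", 20.0)),
        seed=meta.get("seed"),
        afterpulsing=float(meta.get("afterpulsing", 0.0)),
        lifetime_map=gt.get("lifetime_map"),
        photon_map=gt.get("photon_map"),
    )


def gaussian_summary(values: np.ndarray) -> dict:
    """Summarize a lifetime distribution by a Gaussian fit to its histogram.

    Freedman-Diaconis binning; falls back to raw moments when the fit
    cannot be performed.  Raw moments are always reported alongside.
    """
    from scipy.optimize import curve_fit

    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    out = {"n": int(x.size)}
    if x.size == 0:
        out.update(mean=np.nan, std=np.nan, raw_mean=np.nan, raw_std=np.nan, fit="none")
        return out
    out["raw_mean"] = float(x.mean())
    out["raw_std"] = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if x.size < 20 or out["raw_std"] == 0.0:
        out.update(mean=out["raw_mean"], std=out["raw_std"], fit="moments")
        return out
    iqr = float(np.subtract(*np.percentile(x, [75, 25])))
    width = 2.0 * iqr / x.size ** (1.0 / 3.0) if iqr > 0 else 0.0
    span = float(x.max() - x.min())
    n_bins = int(np.ceil(span / width)) if width > 0 else 10
    n_bins = int(np.clip(n_bins, 10, 512))
    hist, edges = np.histogram(x, bins=n_bins)
    centres = 0.5 * (edges[1:] + edges[:-1])

    def gauss(t, amp, mu, sigma):
        return amp * np.exp(-((t - mu) ** 2) / (2.0 * sigma**2))

    try:
        popt, _ = curve_fit(
            gauss,
            centres,
            hist,
            p0=[float(hist.max()), out["raw_mean"], out["raw_std"]],
            maxfev=5000,
        )
        out.update(mean=float(popt[1]), std=float(abs(popt[2])), fit="gaussian")
    except Exception:
        out.update(mean=out["raw_mean"], std=out["raw_std"], fit="moments")
    return out


def write_lifetime_map(lmap: LifetimeMap, path) -> Path:
    """Write tau (float32 TIFF), validity mask and a plain-text summary."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(lmap.tau, dtype=np.float32), photometric="minisblack")
    tifffile.imwrite(
        path.with_name(path.stem + "_mask.tif"),
        lmap.valid.astype(np.uint8),
        photometric="minisblack",
    )
    summary = gaussian_summary(lmap.tau[lmap.valid])
    lines = [f"method\t{lmap.method}"]
    if summary["n"] == 0:
        log.warning("lifetime map %s has no valid pixels", path)
        lines.append("warning\tno valid pixels")
    for key in ("n", "mean", "std", "raw_mean", "raw_std", "fit"):
        lines.append(f"{key}\t{summary[key]}")
    path.with_name(path.stem + "_summary.txt").write_text("\n".join(lines) + "\n")
    return path


def read_lifetime_map(path) -> LifetimeMap:
    path = Path(path)
    tau = tifffile.imread(path).astype(float)
    mask_path = path.with_name(path.stem + "_mask.tif")
    if mask_path.exists():
        valid = tifffile.imread(mask_path).astype(bool)
    else:
        valid = np.isfinite(tau)
    return LifetimeMap(tau=tau, intensity=np.zeros_like(tau), valid=valid)


def write_calibration(params: CalibrationParams, path) -> Path:
    """Plain-text key/value calibration file (YAML)."""
    path = Path(path)
    payload = {
        "A": params.A,
        "B": params.B,
        "C": params.C,
        "b": params.b,
        "windows": list(params.windows),
        "r_squared": params.r_squared,
        "n_repeats": params.n_repeats,
        "seed": params.seed,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
    return path


def read_calibration(path) -> CalibrationParams:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict) or "A" not in payload:
        raise ConfigError(f"{path} is not a calibration file")
    return CalibrationParams(
        A=float(payload["A"]),
        B=float(payload.get("B", 0.0)),
        C=float(payload["C"]),
        b=float(payload.get("b", 20.0)),
        windows=tuple(payload.get("windows", (25.0, 12.5, 6.25))),
        r_squared=payload.get("r_squared"),
        n_repeats=payload.get("n_repeats"),
        seed=payload.get("seed"),
    )
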