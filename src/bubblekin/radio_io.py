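"""Radiograph stack I/O and transmission / optical-depth preprocessing.

The chain implemented here takes raw detector counts to the quantity the
volumetry consumes: the per-pixel *excess optical depth* dtau left after
normalising by the flat field and subtracting the static absorption of
agar, tissue and liquid.  Gas displacing liquid reduces optical depth, so
bubbles appear as positive dtau.

Two flat-field correction methods are provided:

* ``static`` — divide by the mean flat (dark-subtracted), the standard
  normalisation when the illumination is stable.
* ``dynamic`` — per-frame flat synthesised as the best non-negative
  combination of the leading principal components of the flat set,
  fitted on a bubble-free border region of each frame; this follows the
  dynamic (PCA-based) flat-field correction used for synchrotron series
  whose illumination drifts during acquisition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage


@dataclass
class RadiographStack:
    """Calibrated radiograph sequence with its time base.

    frames: (n, h, w) detector counts; flats: (m, h, w); darks: (d, h, w)
    (may be empty, in which case zero dark current is assumed).
    """

    frames: np.ndarray
    times: np.ndarray
    pixel_size_um: float
    flats: np.ndarray
    darks: np.ndarray = field(default_factory=lambda: np.zeros((0, 1, 1)))
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.flats = np.asarray(self.flats, dtype=float)
        self.darks = np.asarray(self.darks, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if len(self.times) != len(self.frames):
            raise ValueError(
                f"{len(self.times)} timestamps for {len(self.frames)} frames"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        if self.flats.ndim != 3 or self.flats.shape[1:] != self.frames.shape[1:]:
            raise ValueError("flats must match frame shape")
        if len(self.darks) and self.darks.shape[1:] != self.frames.shape[1:]:
            raise ValueError("darks must match frame shape")

    @property
    def frame_period_s(self) -> float:
        return float(np.median(np.diff(self.times))) if len(self.times) > 1 else 0.0


@dataclass
class ContextMap:
    """Reference optical depth of agar + tissue + liquid (no bubbles)."""

    tau_ref: np.ndarray
    n_frames_used: int
    method: Literal["static_median", "dynamic"] = "static_median"


@dataclass
class CorrectionResult:
    """Transmission frames with the validity mask and diagnostics."""

    transmission: np.ndarray  # (n, h, w)
    mask: np.ndarray  # (h, w) True where the correction is valid
    method: str
    diagnostics: dict = field(default_factory=dict)


def read_stack(
    path: str | Path,
    timestamps: str | Path | None = None,
    pixel_size_um: float = 25.0,
) -> RadiographStack:
    """Read a simulated or exported run from disk.

    ``path`` may be a directory containing ``frames.tif``/``flats.tif``
    (and optionally ``darks.tif`` and ``timestamps.csv``) or a multi-page
    TIFF of frames with ``timestamps`` given separately.
    """
    import tifffile

    path = Path(path)
    if path.is_dir():
        frame_file = path / "frames.tif"
        if not frame_file.exists():
            raise FileNotFoundError(f"no frames.tif in {path}")
        frames = np.asarray(tifffile.imread(frame_file), dtype=float)
        flat_file = path / "flats.tif"
        if not flat_file.exists():
            raise FileNotFoundError(f"missing flat fields: {flat_file}")
        flats = _as_stack(tifffile.imread(flat_file))
        dark_file = path / "darks.tif"
        darks = (
            _as_stack(tifffile.imread(dark_file))
            if dark_file.exists()
            else np.zeros((0, *frames.shape[1:]))
        )
        if timestamps is None:
            timestamps = path / "timestamps.csv"
    else:
        frames = _as_stack(tifffile.imread(path))
        flats = np.ones((1, *frames.shape[1:]))
        darks = np.zeros((0, *frames.shape[1:]))
    frames = _as_stack(frames)

    if timestamps is None or not Path(timestamps).exists():
        raise FileNotFoundError(f"timestamp table not found: {timestamps}")
    ts = pd.read_csv(timestamps)
    if len(ts) != len(frames):
        missing = sorted(set(range(len(frames))) - set(ts["frame_index"]))
        raise ValueError(
            f"timestamp table has {len(ts)} rows for {len(frames)} frames; "
            f"missing frame indices {missing[:10]}"
        )
    return RadiographStack(
        frames=frames,
        times=ts["time_s"].to_numpy(dtype=float),
        pixel_size_um=pixel_size_um,
        flats=flats,
        darks=darks,
    )


def _as_stack(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    return a[None] if a.ndim == 2 else a


def flat_field_correct(
    stack: RadiographStack,
    method: Literal["static", "dynamic"] = "static",
    n_components: int = 3,
    border_px: int = 8,
) -> CorrectionResult:
    """Normalise detector counts to transmission in roughly [0, 1].

    static: ``T = (I - dark) / (flat - dark)`` with the mean flat/dark.

    dynamic: per-frame flat synthesised from the leading principal
    components of the *log* flat set.  The fit region is a
    ``border_px``-wide frame border assumed bubble-free; because that
    border is still attenuated by liquid and context, its static
    attenuation is first estimated as the temporal median of the
    log-ratio to the mean flat, and the per-frame drift coefficients are
    fitted to what remains.  The multiplicative (log-space) form keeps
    every synthesised flat positive.  Pixels where ``flat - dark <= 0``
    are masked.
    """
    if len(stack.flats) == 0:
        raise ValueError("at least one flat field is required")
    dark = stack.darks.mean(axis=0) if len(stack.darks) else 0.0
    flat_mean = stack.flats.mean(axis=0) - dark
    mask = flat_mean > 0
    if not mask.any():
        raise ValueError("flat-field correction masked every pixel")
    safe_flat = np.where(mask, flat_mean, 1.0)

    frames = stack.frames - dark
    if method == "static":
        trans = frames / safe_flat
        trans[:, ~mask] = 0.0
        return CorrectionResult(trans, mask, "static", {"mask_fraction": float((~mask).mean())})
    if method != "dynamic":
        raise ValueError(f"unknown flat-field method {method!r}")

    # principal drift modes of the log flats around the mean flat
    flats = np.clip(stack.flats - dark, 1e-12, None)
    log_flat_mean = np.log(safe_flat)
    centered = np.log(flats).reshape(len(flats), -1) - log_flat_mean.ravel()
    k = min(n_components, len(flats) - 1) if len(flats) > 1 else 0
    if k > 0:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        modes = vt[:k]
    else:
        modes = np.zeros((0, safe_flat.size))

    border = np.zeros(stack.frames.shape[1:], dtype=bool)
    border[:border_px, :] = border[-border_px:, :] = True
    border[:, :border_px] = border[:, -border_px:] = True
    border &= mask
    bidx = border.ravel()

    with np.errstate(divide="ignore"):
        log_ratio = np.log(np.clip(frames, 1e-12, None)) - log_flat_mean
    # static attenuation of the (bubble-free) border: temporal median of
    # the log ratio, drift assumed zero-median over the run
    border_att = np.median(log_ratio[:, border], axis=0)

    design = np.vstack([np.ones(int(bidx.sum())), modes[:, bidx]]).T  # (nb, k+1)
    trans = np.empty_like(frames)
    coeffs = []
    for i, fr in enumerate(frames):
        resid = log_ratio[i][border] - border_att
        coef, *_ = np.linalg.lstsq(design, resid, rcond=None)
        drift = (coef[0] + coef[1:] @ modes).reshape(fr.shape)
        est_flat = safe_flat * np.exp(drift)
        trans[i] = fr / est_flat
        coeffs.append(coef)
    trans[:, ~mask] = 0.0
    return CorrectionResult(
        trans,
        mask,
        "dynamic",
        {"mask_fraction": float((~mask).mean()), "coefficients": np.array(coeffs)},
    )


def optical_depth(transmission: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """tau = -ln(T); masked or non-positive pixels yield tau = 0."""
    t = np.asarray(transmission, dtype=float)
    valid = t > 0
    if mask is not None:
        valid = valid & mask
    tau = np.zeros_like(t)
    tau[valid] = -np.log(t[valid])
    return tau


def build_context(
    transmission: np.ndarray,
    times: np.ndarray,
    pre_onset_window: tuple[float, float],
    onset_time: float | None = None,
    mask: np.ndarray | None = None,
) -> ContextMap:
    """Per-pixel median optical depth over a bubble-free, pre-onset window.

    ``pre_onset_window`` is (t_start, t_end) in seconds.  The window must
    hold at least 5 frames and must not reach a declared onset.
    """
    times = np.asarray(times, dtype=float)
    t0, t1 = pre_onset_window
    if onset_time is not None and t1 >= onset_time:
        raise ValueError(
            f"context window end {t1} s overlaps bubble onset at {onset_time} s"
        )
    sel = (times >= t0) & (times <= t1)
    if sel.sum() < 5:
        raise ValueError(
            f"context window [{t0}, {t1}] s holds {int(sel.sum())} frames; need >= 5"
        )
    tau = optical_depth(transmission[sel], mask)
    tau_ref = np.clip(np.median(tau, axis=0), 0.0, None)
    return ContextMap(tau_ref=tau_ref, n_frames_used=int(sel.sum()), method="static_median")


def estimate_noise_sigma(
    transmission: np.ndarray,
    context: ContextMap,
    mask: np.ndarray | None = None,
) -> float:
    """Robust per-pixel optical-depth noise from pre-onset residuals.

    Median absolute deviation (scaled to Gaussian sigma) of tau - tau_ref
    over the frames used to build the context.
    """
    tau = optical_depth(transmission, mask)
    resid = tau - context.tau_ref
    if mask is not None:
        resid = resid[:, mask]
    mad = np.median(np.abs(resid - np.median(resid)))
    return float(1.4826 * mad)


def excess_depth(
    tau: np.ndarray,
    context: ContextMap,
    noise_floor: float = 0.0,
    smooth_px: float = 0.0,
) -> tuple[np.ndarray, dict]:
    """Excess optical depth dtau = tau_ref - tau caused by gas.

    Negative excursions (denser than the reference) are clipped to zero
    and counted; values below ``noise_floor`` are set to zero.  An
    optional Gaussian pre-smoothing (``smooth_px`` > 0) trades resolution
    for per-pixel noise before the floor is applied.
    """
    if tau.shape[-2:] != context.tau_ref.shape:
        raise ValueError("frame and context shapes differ")
    dtau = context.tau_ref - tau
    if smooth_px > 0:
        axes = tuple(range(dtau.ndim - 2, dtau.ndim))
        dtau = ndimage.gaussian_filter(dtau, smooth_px, axes=axes)
    n_neg = int((dtau < 0).sum())
    dtau = np.clip(dtau, 0.0, None)
    if noise_floor > 0:
        dtau[dtau < noise_floor] = 0.0
    return dtau, {"n_negative_clipped": n_neg, "noise_floor": noise_floor}


def write_depth_maps(out_path: str | Path, dtau: np.ndarray, diagnostics: dict) -> None:
    """Write dtau maps as 32-bit float TIFF plus a diagnostics JSON."""
    import json

    import tifffile

    out_path = Path(out_path)
    tifffile.imwrite(out_path, np.asarray(dtau, dtype=np.float32), photometric="minisblack")
    with open(out_path.with_suffix(".json"), "w") as fh:
        json.dump({k: v for k, v in diagnostics.items() if np.isscalar(v)}, fh, indent=2)
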