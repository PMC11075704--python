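"""Gas volumetry from excess optical depth, onset detection, bookkeeping.

Direct inversion of the Beer-Lambert law: a pixel whose optical depth
dropped by ``dtau`` relative to the bubble-free reference has a gas path
length ``t_gas = dtau / mu_liq`` along the beam, so the in-field gas
volume of a frame is ``sum(t_gas) * pixel_area``.  No tomography is
involved; the projection itself carries the volume.

Two volume series describe a run: the instantaneous in-field volume
``V(t)`` and the cumulative volume ``V_C(t)``, which adds back the frozen
volume of every bubble that has left the field of view by time t:

    V_C(t) = V(t) + sum over exits with t_exit <= t of V_frozen.

Bubble onset ``t_bo`` is detected as the earliest time the volume exceeds
a threshold (default: a 100 um-diameter sphere, the smallest bubble the
25 um optics can credibly claim) for a persistence of 3 frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .attenuation import AttenuationModel
from .radio_io import ContextMap, optical_depth
from .segmentation import BubbleTrack

#: volume of a 100 um-diameter sphere, mm^3 — the default onset threshold.
DEFAULT_ONSET_THRESHOLD_MM3 = 4.0 / 3.0 * math.pi * 0.05**3


@dataclass
class OnsetEstimate:
    """Detected bubble-onset time and the derived time courses."""

    t_bo: float | None
    detected: bool
    threshold_volume_mm3: float
    persistence_frames: int
    t_ron: float = 0.0

    @property
    def t_bbo(self) -> float | None:
        """Time before bubble onset (dose-accumulation window)."""
        return None if self.t_bo is None else self.t_bo - self.t_ron

    def t_abo(self, t: np.ndarray | float) -> np.ndarray | float:
        """Time after bubble onset."""
        if self.t_bo is None:
            raise ValueError("no onset detected; t_abo undefined")
        return np.asarray(t) - self.t_bo

    def t_rad(self, t: np.ndarray | float) -> np.ndarray | float:
        """Irradiation time."""
        return np.asarray(t) - self.t_ron


@dataclass
class VolumeSeries:
    """Instantaneous and cumulative gas-volume time series (mm^3)."""

    times: np.ndarray
    v: np.ndarray
    v_c: np.ndarray | None = None
    exited_ledger: list[tuple[float, float]] = field(default_factory=list)
    onset: OnsetEstimate | None = None


def gas_volume(
    dtau: np.ndarray, model: AttenuationModel, pixel_size_um: float
) -> tuple[float, np.ndarray]:
    """Invert one excess-depth map to (volume mm^3, gas-thickness map mm)."""
    if model.mu_liq <= 0:
        raise ValueError("mu_liq must be positive")
    if np.any(np.asarray(dtau) < 0):
        raise ValueError("excess depth must be non-negative")
    t_gas = np.asarray(dtau, dtype=float) / model.mu_liq
    px_mm = pixel_size_um / 1000.0
    return float(t_gas.sum() * px_mm**2), t_gas


def volume_series(
    transmission: np.ndarray,
    times: np.ndarray,
    context: ContextMap,
    model: AttenuationModel,
    pixel_size_um: float,
    noise_sigma: float = 0.0,
    mask: np.ndarray | None = None,
    smooth_px: float = 3.0,
    floor_k: float = 5.0,
    high_k: float = 7.0,
    dilate_px: int | None = None,
) -> VolumeSeries:
    """Measure V(t) from corrected transmission frames.

    Per frame the signed excess depth ``tau_ref - tau`` is smoothed, and
    pixels above ``floor_k`` times the post-smoothing noise level (plus a
    morphological dilation to recover the blurred rim) define candidate
    gas support; a candidate blob is kept only if it contains a pixel
    above ``high_k`` sigma (hysteresis), which rejects blobs made of
    noise alone — selecting positive-leaning noise regions would
    otherwise bias the volume upward.  The *unsmoothed, unclipped* excess
    depth is then integrated over the support: summing signed values
    keeps the estimate unbiased, because zero-mean noise inside the
    support cancels instead of rectifying as it would under a hard
    positive floor.
    """
    times = np.asarray(times, dtype=float)
    tau_ref = context.tau_ref
    # white-noise attenuation of a 2D Gaussian filter
    sigma_s = noise_sigma / (2.0 * math.sqrt(math.pi) * smooth_px) if smooth_px > 0 else noise_sigma
    thresh = max(floor_k * sigma_s, 1.0e-9)
    if dilate_px is None:
        dilate_px = int(math.ceil(2 * smooth_px + 2))
    px_mm = pixel_size_um / 1000.0
    v = np.empty(len(times))
    for i in range(len(times)):
        dtau = tau_ref - optical_depth(transmission[i], mask)
        sm = ndimage.gaussian_filter(dtau, smooth_px) if smooth_px > 0 else dtau
        support = sm > thresh
        if support.any() and noise_sigma > 0:
            lbl, n = ndimage.label(support)
            if n:
                peaks = ndimage.maximum(sm, lbl, index=np.arange(1, n + 1))
                keep = np.flatnonzero(peaks > high_k / floor_k * thresh) + 1
                support = np.isin(lbl, keep)
        if support.any():
            support = ndimage.binary_fill_holes(support)
            if dilate_px > 0:
                support = ndimage.binary_dilation(support, iterations=dilate_px)
            if mask is not None:
                support &= mask
            # second-order log bias: for relative intensity noise eps,
            # E[-ln(1+eps)] = +sigma^2/2, so tau is biased high (and dtau
            # low) by sigma^2/2 per pixel; the median-built context does
            # not share the bias.  Add it back over the support.
            bias = support.sum() * noise_sigma**2 / 2.0
            v[i] = (dtau[support].sum() + bias) * px_mm**2 / model.mu_liq
        else:
            v[i] = 0.0
    return VolumeSeries(times=times, v=v)


def detect_onset(
    times: np.ndarray,
    v: np.ndarray,
    threshold_volume: float = DEFAULT_ONSET_THRESHOLD_MM3,
    persistence: int = 3,
    t_ron: float = 0.0,
) -> OnsetEstimate:
    """Earliest time V exceeds the threshold for >= ``persistence`` frames.

    Never raises when no crossing exists: returns an estimate with
    ``detected=False`` (an all-quiet run is a valid outcome).
    """
    times = np.asarray(times, dtype=float)
    v = np.asarray(v, dtype=float)
    above = v > threshold_volume
    run = 0
    for i, a in enumerate(above):
        run = run + 1 if a else 0
        if run >= persistence:
            start = i - persistence + 1
            return OnsetEstimate(
                t_bo=float(times[start]),
                detected=True,
                threshold_volume_mm3=threshold_volume,
                persistence_frames=persistence,
                t_ron=t_ron,
            )
    return OnsetEstimate(
        t_bo=None,
        detected=False,
        threshold_volume_mm3=threshold_volume,
        persistence_frames=persistence,
        t_ron=t_ron,
    )


def accumulate(
    series: VolumeSeries,
    exited_ledger: list[tuple[float, float]] | None = None,
    onset: OnsetEstimate | None = None,
) -> VolumeSeries:
    """Cumulative volume: V_C(t) = V(t) + frozen volumes of earlier exits.

    With a detected onset, V_C is defined as zero before t_bo (pre-onset
    fluctuations are noise, not gas).
    """
    exits = list(exited_ledger or [])
    if exits:
        t0, t1 = series.times[0], series.times[-1]
        for te, _ in exits:
            if not t0 <= te <= t1 + 1.0 / max(len(series.times), 1):
                raise ValueError(f"exit at {te} s outside the series time range")
    v_c = series.v.copy()
    for te, vol in exits:
        v_c[series.times >= te] += vol
    if onset is not None and onset.detected:
        v_c[series.times < onset.t_bo] = 0.0
    return VolumeSeries(
        times=series.times,
        v=series.v,
        v_c=v_c,
        exited_ledger=exits,
        onset=onset if onset is not None else series.onset,
    )


def exits_from_tracks(
    tracks: list[BubbleTrack], model: AttenuationModel, pixel_size_um: float
) -> list[tuple[float, float]]:
    """Exit ledger (time, frozen volume mm^3) from tracked bubbles."""
    px_mm = pixel_size_um / 1000.0
    out = []
    for tr in tracks:
        if tr.status == "exited" and tr.frozen_sum_dtau is not None:
            out.append((float(tr.exit_time), tr.frozen_sum_dtau * px_mm**2 / model.mu_liq))
    return sorted(out)


def cumulative_from_tracks(
    tracks: list[BubbleTrack],
    times: np.ndarray,
    model: AttenuationModel,
    pixel_size_um: float,
) -> np.ndarray:
    """V_C(t) built directly from bubble tracks.

    Each track contributes its measured volume while fully in view and
    its frozen volume — the largest it showed before first touching the
    top edge of the frame — from the touch onward (whatever happens to a
    bubble after it starts leaving is unobservable).  Merge successors
    take over from their parents, so no component is counted twice.
    """
    times = np.asarray(times, dtype=float)
    px_mm = pixel_size_um / 1000.0
    t_index = {round(float(t), 9): i for i, t in enumerate(times)}
    v_c = np.zeros(len(times))
    for tr in tracks:
        vols = np.array([m.sum_dtau for m in tr.measurements]) * px_mm**2 / model.mu_liq
        idx = [t_index[round(m.time_s, 9)] for m in tr.measurements]
        touch = next(
            (j for j, m in enumerate(tr.measurements) if m.bbox_min_row_px == 0), None
        )
        if touch is None:
            for j, i in enumerate(idx):
                v_c[i] += vols[j]
            if tr.status == "exited" and tr.frozen_sum_dtau is not None:
                v_c[times >= tr.exit_time] += (
                    tr.frozen_sum_dtau * px_mm**2 / model.mu_liq
                )
        else:
            for j, i in enumerate(idx[:touch]):
                v_c[i] += vols[j]
            frozen = float(vols[: max(touch, 1)].max())
            v_c[times >= tr.measurements[touch].time_s] += frozen
    return v_c


def excess_volume(
    series_a: VolumeSeries,
    series_b: VolumeSeries,
    min_overlap_s: float = 60.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Difference of two cumulative series after onset alignment.

    Both series are re-based to t_abo = 0 at their own detected onsets,
    resampled onto a common grid, and subtracted (a minus b; pass the
    non-degassed series first to get the degassing excess).
    """
    for s in (series_a, series_b):
        if s.onset is None or not s.onset.detected:
            raise ValueError("both series need a detected onset")
        if s.v_c is None:
            raise ValueError("accumulate() both series before differencing")
    ta = series_a.times - series_a.onset.t_bo
    tb = series_b.times - series_b.onset.t_bo
    lo, hi = max(ta[0], tb[0]), min(ta[-1], tb[-1])
    if hi - lo < min_overlap_s:
        raise ValueError(
            f"post-onset overlap {hi - lo:.1f} s is shorter than {min_overlap_s} s"
        )
    step = min(np.median(np.diff(ta)), np.median(np.diff(tb)))
    grid = np.arange(lo, hi + step / 2, step)
    va = np.interp(grid, ta, series_a.v_c)
    vb = np.interp(grid, tb, series_b.v_c)
    return grid, va - vb
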