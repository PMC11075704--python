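"""Bubble detection, tracking and shape-based growth classification.

Bubbles are connected components of positive excess optical depth.  Shape
is summarised by the circularity ``4*pi*A / C**2`` (1 for a circle,
falling towards 0 with eccentricity), the descriptor that separates the
three growth regimes seen in wet-embedded tissue:

* unconstrained growth in agar gaps keeps circularity near 1;
* growth along a tubular vessel elongates the silhouette, so circularity
  decreases steadily;
* growth through a multi-compartment air space (alveoli) produces a
  stepped area curve with plateaus between compartment fills.

Perimeters use the Crofton formula (4 directions), whose small-shape bias
is far below the raw pixel-edge count that would otherwise deflate the
circularity of genuinely round bubbles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import ndimage, stats
from skimage import measure, morphology


@dataclass
class BubbleMeasurement:
    """Per-frame measurement of one segmented bubble."""

    label: int
    frame: int
    time_s: float
    area_um2: float
    perimeter_um: float
    circularity: float
    centroid_um: tuple[float, float]  # (x, y)
    mean_dtau: float
    sum_dtau: float  # sum of excess depth over the component (for volumes)
    n_pixels: int
    bbox_min_row_px: int = 1  # 0 means the component touches the top edge


@dataclass
class BubbleTrack:
    """One bubble followed through time."""

    track_id: int
    measurements: list[BubbleMeasurement] = field(default_factory=list)
    birth_time: float = 0.0
    status: Literal["active", "exited", "merged"] = "active"
    exit_time: float | None = None
    frozen_sum_dtau: float | None = None
    merged_into: int | None = None
    parents: tuple[int, ...] = ()
    anomaly: bool = False  # disappeared away from the top edge

    @property
    def times(self) -> np.ndarray:
        return np.array([m.time_s for m in self.measurements])

    @property
    def areas_um2(self) -> np.ndarray:
        return np.array([m.area_um2 for m in self.measurements])

    @property
    def circularities(self) -> np.ndarray:
        return np.array([m.circularity for m in self.measurements])

    def __len__(self) -> int:
        return len(self.measurements)


def segment_frame(
    dtau: np.ndarray,
    pixel_size_um: float,
    min_size_px: int = 10,
    frame: int = 0,
    time_s: float = 0.0,
) -> tuple[np.ndarray, list[BubbleMeasurement]]:
    """Segment one excess-depth map into labelled bubbles.

    Pixels above zero (the noise floor is applied upstream) are grouped
    into connected components; holes are filled and components smaller
    than ``min_size_px`` discarded.  Area comes from the pixel count,
    perimeter from the Crofton estimator.
    """
    if np.any(dtau < 0):
        raise ValueError("excess-depth map must be non-negative")
    binary = dtau > 0
    if not binary.any():
        return np.zeros(dtau.shape, dtype=int), []
    binary = ndimage.binary_fill_holes(binary)
    binary = morphology.remove_small_objects(binary, max_size=min_size_px - 1)
    labels = measure.label(binary, connectivity=2)
    out = []
    for rp in measure.regionprops(labels, intensity_image=dtau):
        area = rp.area * pixel_size_um**2
        perim = rp.perimeter_crofton * pixel_size_um
        if perim <= 0:
            continue
        cy, cx = rp.centroid
        out.append(
            BubbleMeasurement(
                label=rp.label,
                frame=frame,
                time_s=time_s,
                area_um2=float(area),
                perimeter_um=float(perim),
                circularity=float(4 * np.pi * area / perim**2),
                centroid_um=(float(cx * pixel_size_um), float(cy * pixel_size_um)),
                mean_dtau=float(rp.intensity_mean),
                sum_dtau=float(rp.intensity_mean * rp.area),
                n_pixels=int(rp.area),
                bbox_min_row_px=int(rp.bbox[0]),
            )
        )
    return labels, out


def segment_stack(
    dtau_frames: np.ndarray,
    times: np.ndarray,
    pixel_size_um: float,
    min_size_px: int = 10,
) -> tuple[list[np.ndarray], list[list[BubbleMeasurement]]]:
    """Segment every frame of a stack; convenience wrapper."""
    labels_list, meas_list = [], []
    for fi, (fr, t) in enumerate(zip(dtau_frames, times)):
        labels, meas = segment_frame(fr, pixel_size_um, min_size_px, frame=fi, time_s=float(t))
        labels_list.append(labels)
        meas_list.append(meas)
    return labels_list, meas_list


def track_bubbles(
    labels_list: Sequence[np.ndarray],
    measurements_list: Sequence[list[BubbleMeasurement]],
    times: np.ndarray,
    top_margin_px: int = 10,
    pixel_size_um: float | None = None,
) -> list[BubbleTrack]:
    """Link per-frame components into tracks by maximal pixel overlap.

    A track whose component disappears while its last centroid lies
    within ``top_margin_px`` of the top edge is marked ``exited`` (the
    bubble migrated out through the top); its exit time is one frame
    period after it was last seen and its excess-depth integral is frozen
    at the largest value over its last three frames (the last frame may
    catch the bubble only partially in view).  Two tracks claiming the
    same component are closed as ``merged`` and a successor track
    continues from the merge.  Disappearances away from the top edge are
    flagged as anomalies.
    """
    times = np.asarray(times, dtype=float)
    if len(labels_list) != len(times) or len(measurements_list) != len(times):
        raise ValueError("labels, measurements and times must align")
    period = float(np.median(np.diff(times))) if len(times) > 1 else 0.0
    tracks: list[BubbleTrack] = []
    active: dict[int, int] = {}  # current component label -> track index

    for fi, (labels, meas) in enumerate(zip(labels_list, measurements_list)):
        meas_by_label = {m.label: m for m in meas}
        if fi == 0:
            for m in meas:
                tracks.append(
                    BubbleTrack(
                        track_id=len(tracks),
                        measurements=[m],
                        birth_time=float(times[0] - period),
                    )
                )
                active[m.label] = tracks[-1].track_id
            continue

        prev_labels = labels_list[fi - 1]
        # overlap histogram between consecutive label images
        both = (prev_labels > 0) & (labels > 0)
        pairs: dict[int, dict[int, int]] = {}
        if both.any():
            pl, cl = prev_labels[both], labels[both]
            flat = pl.astype(np.int64) * (labels.max() + 1) + cl
            uniq, counts = np.unique(flat, return_counts=True)
            for u, c in zip(uniq, counts):
                p, q = divmod(int(u), labels.max() + 1)
                pairs.setdefault(p, {})[q] = int(c)

        claims: dict[int, list[int]] = {}  # new label -> claiming track ids
        for plabel, tid in sorted(active.items(), key=lambda kv: kv[1]):
            overl = pairs.get(plabel, {})
            if overl:
                best = max(sorted(overl), key=lambda q: overl[q])
                claims.setdefault(best, []).append(tid)
            else:
                _close_track(tracks[tid], times, fi, period, top_margin_px, pixel_size_um)
        new_active: dict[int, int] = {}
        for new_label, tids in claims.items():
            m = meas_by_label.get(new_label)
            if m is None:
                continue
            if len(tids) == 1:
                tracks[tids[0]].measurements.append(m)
                new_active[new_label] = tids[0]
            else:  # merge: close parents, spawn successor
                succ = BubbleTrack(
                    track_id=len(tracks),
                    measurements=[m],
                    birth_time=min(tracks[t].birth_time for t in tids),
                    parents=tuple(sorted(tids)),
                )
                tracks.append(succ)
                for t in tids:
                    tracks[t].status = "merged"
                    tracks[t].merged_into = succ.track_id
                new_active[new_label] = succ.track_id
        for m in meas:  # unclaimed components are newborn bubbles
            if m.label not in new_active:
                tracks.append(
                    BubbleTrack(
                        track_id=len(tracks),
                        measurements=[m],
                        birth_time=float(times[fi] - period),
                    )
                )
                new_active[m.label] = tracks[-1].track_id
        active = new_active
    return tracks


def _close_track(
    track: BubbleTrack,
    times: np.ndarray,
    frame_idx: int,
    period: float,
    top_margin_px: int,
    pixel_size_um: float | None,
) -> None:
    if track.status != "active":
        return
    last = track.measurements[-1]
    px = pixel_size_um if pixel_size_um is not None else 25.0
    near_top = last.centroid_um[1] <= top_margin_px * px
    if near_top:
        track.status = "exited"
        track.exit_time = float(last.time_s + period)
        # the final frames may catch the bubble only partially in view, so
        # freeze the largest integral the track ever showed (bubbles grow
        # monotonically until they leave)
        track.frozen_sum_dtau = float(max(m.sum_dtau for m in track.measurements))
    else:
        track.anomaly = True
        track.exit_time = float(last.time_s + period)


# ---------------------------------------------------------------------------
# Growth classification
# ---------------------------------------------------------------------------


def _piecewise_constant_sse(y: np.ndarray, max_changepoints: int, factor: float) -> tuple[float, int]:
    """Greedy binary segmentation: add the best changepoint while it
    shrinks the total squared error by at least ``factor``."""
    segments = [(0, len(y))]
    sse = [_sse_const(y)]
    n_cp = 0
    while n_cp < max_changepoints:
        best = None
        for si, (a, b) in enumerate(segments):
            if b - a < 4:
                continue
            seg = y[a:b]
            csum = np.cumsum(seg)
            csq = np.cumsum(seg**2)
            n = b - a
            for cut in range(2, n - 1):
                left = csq[cut - 1] - csum[cut - 1] ** 2 / cut
                right = (csq[-1] - csq[cut - 1]) - (csum[-1] - csum[cut - 1]) ** 2 / (n - cut)
                gain = sse[si] - (left + right)
                if best is None or gain > best[0]:
                    best = (gain, si, cut, left, right)
        if best is None or best[0] <= 0:
            break
        gain, si, cut, left, right = best
        total = sum(sse)
        new_total = total - gain
        # keep splitting only while the whole fit improves by >= factor
        if new_total > 0 and total / new_total < factor:
            break
        a, b = segments[si]
        segments[si : si + 1] = [(a, a + cut), (a + cut, b)]
        sse[si : si + 1] = [left, right]
        n_cp += 1
    return float(sum(sse)), n_cp


def _sse_const(y: np.ndarray) -> float:
    return float(np.sum((y - y.mean()) ** 2))


def _sse_linear(t: np.ndarray, y: np.ndarray) -> float:
    coef = np.polyfit(t, y, 1)
    return float(np.sum((y - np.polyval(coef, t)) ** 2))


def classify_growth(
    track: BubbleTrack,
    eps: float = 1.0e-3,
    circ_threshold: float = 0.85,
    plateau_factor: float = 2.0,
    max_changepoints: int = 4,
) -> str:
    """Classify a track as unconstrained / vessel_confined / alveolar_stepped.

    Rules, applied to the circularity and area time series:

    * ``alveolar_stepped`` — the area curve is better described by >= 2
      plateaus: a piecewise-constant fit with at least two changepoints
      beats the best straight line by ``plateau_factor`` in squared error.
    * ``unconstrained`` — circularity stays high (10th percentile above
      ``circ_threshold``) with negligible robust trend (|Theil-Sen slope|
      < ``eps`` per second).
    * ``vessel_confined`` — circularity decreases steadily (robust slope
      < -``eps``) without area plateaus.
    * anything else is reported ``unclassified``.
    """
    if len(track) < 10:
        raise ValueError(f"track {track.track_id} has {len(track)} frames; need >= 10")
    t = track.times
    area = track.areas_um2
    circ = track.circularities

    pc_sse, n_cp = _piecewise_constant_sse(area, max_changepoints, plateau_factor)
    lin_sse = _sse_linear(t, area)
    stepped = n_cp >= 2 and pc_sse * plateau_factor <= lin_sse
    if stepped:
        return "alveolar_stepped"

    slope = stats.theilslopes(circ, t).slope
    if np.percentile(circ, 10) > circ_threshold and abs(slope) < eps:
        return "unconstrained"
    if slope < -eps:
        return "vessel_confined"
    return "unclassified"


def count_area_steps(
    track: BubbleTrack, plateau_factor: float = 2.0, max_changepoints: int = 6
) -> int:
    """Number of accepted changepoints in the area curve (step count)."""
    _, n_cp = _piecewise_constant_sse(track.areas_um2, max_changepoints, plateau_factor)
    return n_cp


def estimate_birth_time(track: BubbleTrack, n_points: int = 10) -> float:
    """Refine a track's birth time by extrapolating its area to zero.

    The first detection lags nucleation (the bubble must outgrow the
    noise floor and the minimum size), which distorts log-log growth fits
    at small t_abo.  A robust line through the earliest area samples,
    extrapolated to zero area, recovers the nucleation time for any
    silhouette whose area initially grows about linearly.  The estimate
    is clamped to at most one frame period after first detection and to
    ten periods before it.
    """
    t = track.times
    a = track.areas_um2
    n = min(max(n_points, 3), len(t))
    res = stats.theilslopes(a[:n], t[:n])
    period = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    if res.slope <= 0:
        return track.birth_time
    t0 = -res.intercept / res.slope
    return float(np.clip(t0, t[0] - 10 * period, t[0] + period))


def area_growth_exponent(
    track: BubbleTrack, birth: Literal["extrapolate", "track"] = "extrapolate"
) -> tuple[float, float]:
    """Least-squares slope of log(area) vs log(t_abo) with standard error.

    ``t_abo`` counts from the birth time — by default re-estimated by
    zero-area extrapolation (see :func:`estimate_birth_time`), otherwise
    the tracker's first-seen estimate.  Non-positive areas or times are
    excluded with a warning.
    """
    t0 = estimate_birth_time(track) if birth == "extrapolate" else track.birth_time
    t_abo = track.times - t0
    area = track.areas_um2
    good = (t_abo > 0) & (area > 0)
    if good.sum() < len(area):
        warnings.warn(
            f"excluded {int((~good).sum())} non-positive samples from growth fit"
        )
    if good.sum() < 10:
        raise ValueError("need >= 10 points with positive area and t_abo")
    res = stats.linregress(np.log(t_abo[good]), np.log(area[good]))
    return float(res.slope), float(res.stderr)
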