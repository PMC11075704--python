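"""Micro-gas-chromatography quantification: peaks to relative concentrations.

A portable micro-GC samples the headspace around the sample container once
per elution round (about 2.4 min).  Two of its four columns carry the
species of interest: the molecular-sieve module (MS5A) separates the fixed
gases N2 and O2, and the PDMS10 module carries the solvent vapours EtOH
and H2O plus one combined N2+O2 peak.  The remaining modules (PDMS5, PPU)
are ingested and stored but not quantified by default.

Per cycle, each chromatogram is baseline-corrected, peaks are matched to a
reference retention-time table, integrated, and expressed as within-module
relative concentrations (peak-area fractions summing to one).  An
onset-aligned summary classifies each species as increasing, decreasing
or unchanged across bubble onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

DEFAULT_CYCLE_PERIOD_S = 144.0  # one elution round through the four modules

#: reference retention times per module, seconds.  These are configuration
#: data in real use (they depend on column and carrier-gas settings); the
#: defaults match the bundled phantom.
DEFAULT_RETENTION_S: dict[str, dict[str, float]] = {
    "MS5A": {"N2": 35.0, "O2": 55.0},
    "PDMS10": {"N2+O2": 20.0, "H2O": 45.0, "EtOH": 70.0},
}

QUANTIFIED_MODULES = ("MS5A", "PDMS10")

#: offsets (s) of the onset-aligned report: 6 and 3 minutes before onset,
#: 5 and 10 minutes after it.
ONSET_WINDOW_OFFSETS_S = (-360.0, -180.0, 300.0, 600.0)


@dataclass
class Chromatogram:
    """One detection module's trace for one elution cycle."""

    module: str
    cycle_index: int
    cycle_time_s: float  # midpoint of the elution round
    retention_time_s: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.retention_time_s = np.asarray(self.retention_time_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if np.any(np.diff(self.retention_time_s) <= 0):
            raise ValueError("retention_time axis must be strictly increasing")
        if len(self.retention_time_s) != len(self.signal):
            raise ValueError("retention_time and signal lengths differ")


@dataclass
class PeakTable:
    """Integrated peaks of one chromatogram."""

    module: str
    cycle_index: int
    cycle_time_s: float
    peaks: pd.DataFrame  # species, apex_rt_s, area, ambiguous
    noise_sigma: float = 0.0


def correct_baseline(chrom: Chromatogram, window: int = 41, n_iter: int = 3) -> Chromatogram:
    """Subtract a slowly varying baseline from a chromatogram.

    Iterative rolling-minimum estimate: a minimum filter of ``window``
    samples followed by a smoothing mean, never allowed to exceed the
    signal, repeated ``n_iter`` times.  Because the rolling minimum of a
    noisy trace sits a couple of noise sigma *below* the true baseline,
    the corrected trace is re-centred on its own median (peaks occupy a
    minor fraction of the retention axis, so the median tracks the
    off-peak level).  Peaks narrow relative to the window are left
    intact within ~2%.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    n = len(chrom.signal)
    if window > n:
        raise ValueError(f"baseline window {window} exceeds trace length {n}")
    base = chrom.signal.astype(float).copy()
    for _ in range(n_iter):
        rolled = ndimage.minimum_filter1d(base, size=window, mode="nearest")
        rolled = ndimage.uniform_filter1d(rolled, size=window, mode="nearest")
        base = np.minimum(base, rolled)
    corrected = chrom.signal - base
    corrected = corrected - np.median(corrected)
    return Chromatogram(
        module=chrom.module,
        cycle_index=chrom.cycle_index,
        cycle_time_s=chrom.cycle_time_s,
        retention_time_s=chrom.retention_time_s,
        signal=corrected,
    )


def _noise_sigma(y: np.ndarray) -> float:
    """Robust noise estimate from the median absolute deviation."""
    return float(1.4826 * np.median(np.abs(y - np.median(y))))


def integrate_peaks(
    chrom: Chromatogram,
    reference_rt: dict[str, float] | None = None,
    tolerance_s: float = 5.0,
    snr: float = 5.0,
) -> PeakTable:
    """Detect, assign and integrate peaks in a baseline-corrected trace.

    Local maxima above ``snr`` times the robust noise level are matched to
    the nearest reference retention time within ``tolerance_s``; peaks
    matching no reference stay ``unassigned``.  Areas are trapezoidal
    integrals over the contiguous above-baseline support of each peak.
    When two maxima claim one reference the larger area wins and the
    assignment is flagged ambiguous.
    """
    if reference_rt is None:
        reference_rt = DEFAULT_RETENTION_S.get(chrom.module, {})
    rt, y = chrom.retention_time_s, chrom.signal
    sigma = _noise_sigma(y)
    height = max(snr * sigma, 1e-12)
    idx, _ = signal.find_peaks(y, height=height)
    support_level = max(0.5 * sigma, 1e-12)
    rows = []
    for i in idx:
        lo = i
        while lo > 0 and y[lo - 1] > support_level:
            lo -= 1
        hi = i
        while hi < len(y) - 1 and y[hi + 1] > support_level:
            hi += 1
        area = float(np.trapezoid(y[lo : hi + 1], rt[lo : hi + 1]))
        apex = float(rt[i])
        species = "unassigned"
        if reference_rt:
            name, ref = min(reference_rt.items(), key=lambda kv: abs(kv[1] - apex))
            if abs(ref - apex) <= tolerance_s:
                species = name
        rows.append({"species": species, "apex_rt_s": apex, "area": area, "ambiguous": False})
    peaks = pd.DataFrame(rows, columns=["species", "apex_rt_s", "area", "ambiguous"])
    # resolve duplicate assignments: largest area keeps the species
    for sp, grp in peaks[peaks.species != "unassigned"].groupby("species"):
        if len(grp) > 1:
            keep = grp["area"].idxmax()
            drop = grp.index.difference([keep])
            peaks.loc[drop, "species"] = "unassigned"
            peaks.loc[keep, "ambiguous"] = True
    if (peaks["area"] < 0).any():
        raise ValueError("negative peak area; baseline correction failed")
    return PeakTable(
        module=chrom.module,
        cycle_index=chrom.cycle_index,
        cycle_time_s=chrom.cycle_time_s,
        peaks=peaks,
        noise_sigma=sigma,
    )


@dataclass
class ConcentrationSeries:
    """Per-module, per-species relative concentrations vs cycle time.

    ``table`` columns: module, cycle_index, cycle_time_s, species,
    fraction.  Fractions are normalised within module and cycle over the
    assigned species; cycles with zero total assigned area are flagged in
    ``flagged_cycles`` and excluded from the table.
    """

    table: pd.DataFrame
    flagged_cycles: list[tuple[str, int]] = field(default_factory=list)


def relative_concentrations(tables: list[PeakTable]) -> ConcentrationSeries:
    """Normalise assigned peak areas to within-cycle fractions."""
    rows = []
    flagged = []
    for pt in tables:
        assigned = pt.peaks[pt.peaks.species != "unassigned"]
        total = assigned["area"].sum()
        if total <= 0:
            flagged.append((pt.module, pt.cycle_index))
            continue
        for _, r in assigned.iterrows():
            rows.append(
                {
                    "module": pt.module,
                    "cycle_index": pt.cycle_index,
                    "cycle_time_s": pt.cycle_time_s,
                    "species": r.species,
                    "fraction": r.area / total,
                }
            )
    table = pd.DataFrame(
        rows, columns=["module", "cycle_index", "cycle_time_s", "species", "fraction"]
    )
    return ConcentrationSeries(table=table, flagged_cycles=flagged)


def onset_window_summary(
    series: ConcentrationSeries,
    t_bo: float,
    cycle_period_s: float = DEFAULT_CYCLE_PERIOD_S,
    offsets_s: tuple[float, ...] = ONSET_WINDOW_OFFSETS_S,
    min_delta: float = 0.01,
) -> pd.DataFrame:
    """Onset-aligned species report: spot values, pre/post means, trend.

    For each module/species: the fraction at each offset (nearest cycle
    within half a period, else missing), the mean over pre-onset and
    post-onset cycles, their difference, and a classification —
    ``increasing`` if the post-pre difference exceeds the cycle-to-cycle
    noise, ``decreasing`` if below its negative, else ``unchanged``.
    ``min_delta`` floors the decision threshold: a shift smaller than 1%
    concentration is never called a trend, however quiet the series.
    """
    df = series.table
    out = []
    for (module, sp), grp in df.groupby(["module", "species"]):
        grp = grp.sort_values("cycle_time_s")
        t = grp["cycle_time_s"].to_numpy()
        f = grp["fraction"].to_numpy()
        row: dict = {"module": module, "species": sp}
        for off in offsets_s:
            target = t_bo + off
            j = int(np.argmin(np.abs(t - target))) if len(t) else -1
            if j >= 0 and abs(t[j] - target) <= cycle_period_s / 2:
                row[f"at_{int(off)}s"] = float(f[j])
            else:
                row[f"at_{int(off)}s"] = np.nan
        pre, post = f[t < t_bo], f[t >= t_bo]
        # cycle-to-cycle noise from successive differences (trend-robust)
        diffs = np.diff(pre) if len(pre) > 2 else np.diff(f)
        sigma = float(np.std(diffs) / np.sqrt(2)) if len(diffs) else 0.0
        pre_mean = float(pre.mean()) if len(pre) else np.nan
        post_mean = float(post.mean()) if len(post) else np.nan
        delta = post_mean - pre_mean
        gate = max(sigma, min_delta)
        if np.isnan(delta):
            trend = "missing"
        elif delta > gate:
            trend = "increasing"
        elif delta < -gate:
            trend = "decreasing"
        else:
            trend = "unchanged"
        row.update(
            pre_mean=pre_mean,
            post_mean=post_mean,
            difference=delta,
            noise_sigma=sigma,
            trend=trend,
        )
        out.append(row)
    return pd.DataFrame(out)


def analyse_chromatograms(
    chromatograms: list[Chromatogram],
    reference_rt: dict[str, dict[str, float]] | None = None,
    baseline_window: int = 41,
    modules: tuple[str, ...] = QUANTIFIED_MODULES,
) -> ConcentrationSeries:
    """Full chain: baseline -> peaks -> relative concentrations."""
    refs = reference_rt or DEFAULT_RETENTION_S
    tables = [
        integrate_peaks(correct_baseline(ch, baseline_window), refs.get(ch.module))
        for ch in chromatograms
        if ch.module in modules
    ]
    return relative_concentrations(tables)


def read_chromatograms(path) -> list[Chromatogram]:
    """Read the long-format chromatogram CSV the phantom writes."""
    df = pd.read_csv(path)
    out = []
    for (module, ci), grp in df.groupby(["module", "cycle_index"]):
        grp = grp.sort_values("retention_time_s")
        out.append(
            Chromatogram(
                module=str(module),
                cycle_index=int(ci),
                cycle_time_s=float(grp["cycle_time_s"].iloc[0]),
                retention_time_s=grp["retention_time_s"].to_numpy(),
                signal=grp["signal"].to_numpy(),
            )
        )
    return out
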