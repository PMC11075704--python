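"""Synthetic cineradiography and micro-GC phantom with exported ground truth.

The generator emulates the data a synchrotron bubble-formation experiment
produces: a time series of parallel-beam radiographs of a liquid-filled
container (70% ethanol + crushed agar + tissue context) in which gas
bubbles nucleate sequentially and grow, plus per-cycle gas chromatograms
whose solvent fractions shift when bubbling starts.

Bubbles follow one of three growth laws, one per microstructure regime:

* ``diffusion`` — unconstrained growth in an agar gap: a sphere whose
  radius grows as the square root of the time since nucleation, so the
  projected area grows linearly in time.
* ``vessel_bidirectional`` — growth inside a tubular vessel: a capsule
  (cylinder with hemispherical caps) of fixed radius elongating linearly
  in both directions; its silhouette is a stadium.
* ``alveolar_stepped`` — growth through a multi-compartment air space:
  adjacent spherical compartments fill one after another, giving a
  stepped, plateau-rich area and volume curve.

Everything the analysis later estimates (volumes, areas, perimeters, exit
events, onset time) is also written to a ground-truth ledger so the
pipeline can be validated end to end.

Rendering follows the Beer-Lambert law for a monochromatic effective
energy: ``I = flat * exp(-tau_bg + mu_liq * t_gas) + dark + noise`` where
``t_gas`` is the beam path length through gas (gas displaces attenuating
liquid, so bubbles brighten the image).  An optional edge-enhancement term
proportional to the discrete Laplacian of ``t_gas`` mimics propagation
fringes; it defaults to off because the analysis never inverts phase.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator
from scipy import ndimage

from .attenuation import MU_LIQ_MM
from .gc_analysis import DEFAULT_RETENTION_S, Chromatogram
from .radio_io import RadiographStack

# ---------------------------------------------------------------------------
# Specifications
# ---------------------------------------------------------------------------


class PhantomSpec(BaseModel):
    """Geometry, optics and noise of one synthetic cineradiography run.

    Defaults reproduce the acquisition this package targets: a 50 mm x 4 mm
    field of view sampled at an isotropic 25 um pixel size, 3 frames per
    second, parallel beam.
    """

    field_of_view_mm: tuple[float, float] = (50.0, 4.0)  # (width, height)
    pixel_size_um: float = Field(25.0, gt=0)
    frame_rate_hz: float = Field(3.0, gt=0)
    duration_s: float = Field(60.0, gt=0)
    #: beam-path length through the liquid column (container depth).
    container_thickness_mm: float = Field(70.0, gt=0)
    microstructure: Literal["none", "agar_gaps", "vessel", "alveolar"] = "agar_gaps"
    vessel_diameter_um: float = Field(100.0, gt=0)
    vessel_center_frac: float = Field(0.5, ge=0.0, le=1.0)
    alveolus_radius_um: float = Field(125.0, gt=0)
    #: amplitude (optical depth) and correlation length of the smooth
    #: agar/tissue context added on top of the uniform liquid column.
    context_amplitude: float = Field(0.25, ge=0)
    context_scale_mm: float = Field(2.0, gt=0)
    mu_liq_mm: float = Field(MU_LIQ_MM, gt=0)
    noise_rel: float = Field(0.0, ge=0)  # relative Gaussian intensity noise
    photon_scale: float = Field(10000.0, gt=0)  # flat-field count level
    dark_level: float = Field(0.0, ge=0)
    fringe_strength: float = Field(0.0, ge=0)
    #: relative amplitude of a slow illumination drift (exercises the
    #: dynamic flat-field correction); 0 keeps the flat constant in time.
    flat_drift: float = Field(0.0, ge=0)
    n_flats: int = Field(10, ge=1)
    n_darks: int = Field(0, ge=0)
    seed: int = 0

    @model_validator(mode="after")
    def _check_geometry(self) -> "PhantomSpec":
        w, h = self.field_of_view_mm
        if w <= 0 or h <= 0:
            raise ValueError("field of view dimensions must be positive")
        if self.microstructure == "vessel" and self.vessel_diameter_um / 1000.0 > h:
            raise ValueError("vessel diameter exceeds the field-of-view height")
        if self.microstructure == "alveolar" and 2 * self.alveolus_radius_um / 1000.0 > h:
            raise ValueError("alveolus diameter exceeds the field-of-view height")
        return self

    @property
    def pixel_size_mm(self) -> float:
        return self.pixel_size_um / 1000.0

    @property
    def shape(self) -> tuple[int, int]:
        """Frame shape (rows, cols)."""
        w, h = self.field_of_view_mm
        return (max(1, round(h / self.pixel_size_mm)), max(1, round(w / self.pixel_size_mm)))

    def times(self) -> np.ndarray:
        """Frame time base in seconds, t = 0 at radiation-on."""
        n = int(round(self.duration_s * self.frame_rate_hz))
        return np.arange(n) / self.frame_rate_hz


@dataclass
class BubbleSeed:
    """One bubble: where and when it nucleates, and how it grows.

    ``law_parameters`` keys by law:

    * diffusion: ``growth_rate`` (mm s^-0.5), radius = rate * sqrt(t_abo)
    * vessel_bidirectional: ``radius_mm``, ``elongation_rate`` (mm/s,
      total length growth, split over both directions)
    * alveolar_stepped: ``radius_mm``, ``n_compartments``, ``dwell_s``,
      ``fill_s``
    """

    nucleation_time: float
    site: tuple[float, float]  # (x_mm, y_mm), origin top-left
    growth_law: Literal["diffusion", "vessel_bidirectional", "alveolar_stepped"]
    law_parameters: dict[str, float] = field(default_factory=dict)
    #: constant upward drift starting at ``rise_start``; lets a bubble
    #: migrate to the top and leave the field of view (an exit event).
    rise_speed_mm_s: float = 0.0
    rise_start: float | None = None
    bubble_id: int = 0

    def __post_init__(self) -> None:
        if self.nucleation_time < 0:
            raise ValueError("nucleation_time must be >= 0")
        for key, value in self.law_parameters.items():
            if key != "n_compartments" and value <= 0:
                raise ValueError(f"law parameter {key!r} must be positive")
        if self.rise_speed_mm_s < 0:
            raise ValueError("rise_speed_mm_s must be >= 0")


@dataclass
class GasSchedule:
    """Injected gas amounts per elution cycle for the chromatogram phantom.

    Solvent fractions shift at ``onset_time_s``: cycles whose midpoint
    falls after onset use ``post_fractions``.  Amount units are arbitrary
    detector units; only relative concentrations are analysed downstream.
    """

    n_cycles: int = 12
    cycle_period_s: float = 144.0  # one elution round through all modules
    onset_time_s: float = 720.0
    pre_fractions: dict[str, float] = field(
        default_factory=lambda: {"N2": 0.50, "O2": 0.14, "EtOH": 0.14, "H2O": 0.22}
    )
    post_fractions: dict[str, float] = field(
        default_factory=lambda: {"N2": 0.50, "O2": 0.14, "EtOH": 0.26, "H2O": 0.10}
    )
    total_amount: float = 100.0
    baseline_level: float = 2.0
    baseline_drift: float = 0.5
    noise_sigma: float = 0.02
    peak_width_s: float = 2.0
    retention_s: dict[str, dict[str, float]] = field(
        default_factory=lambda: {m: dict(t) for m, t in DEFAULT_RETENTION_S.items()}
    )
    rt_max_s: float = 100.0
    rt_step_s: float = 0.25

    def __post_init__(self) -> None:
        if self.cycle_period_s <= 0:
            raise ValueError("cycle_period_s must be positive")
        for fr in (self.pre_fractions, self.post_fractions):
            if any(v < 0 for v in fr.values()):
                raise ValueError("fractions must be non-negative")

    def cycle_times(self) -> np.ndarray:
        """Midpoint time of each elution round, seconds."""
        return (np.arange(self.n_cycles) + 0.5) * self.cycle_period_s

    def amounts(self, cycle_time: float) -> dict[str, float]:
        fr = self.post_fractions if cycle_time >= self.onset_time_s else self.pre_fractions
        total = sum(fr.values())
        return {sp: self.total_amount * v / total for sp, v in fr.items()}


# ---------------------------------------------------------------------------
# Phantom construction
# ---------------------------------------------------------------------------


@dataclass
class Phantom:
    """Static scene: background optical depth and microstructure mask."""

    spec: PhantomSpec
    tau_bg: np.ndarray  # per-pixel optical depth of liquid + context
    mask: np.ndarray  # True where void space allows bubble growth
    compartment_centers: list[tuple[float, float]] = field(default_factory=list)


def _pixel_grid_mm(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    ny, nx = spec.shape
    px = spec.pixel_size_mm
    y = (np.arange(ny) + 0.5) * px
    x = (np.arange(nx) + 0.5) * px
    return np.meshgrid(x, y)  # (X, Y) each (ny, nx)


def build_phantom(spec: PhantomSpec) -> Phantom:
    """Build the background optical-depth map and the microstructure mask.

    The background is the uniform liquid column, ``mu_liq * thickness``,
    plus a smooth random field standing in for the agar/tissue context.
    The mask marks void spaces (agar gaps / vessel lumen / alveoli) where
    bubbles may grow.
    """
    ny, nx = spec.shape
    rng = np.random.default_rng(spec.seed)
    tau = np.full((ny, nx), spec.mu_liq_mm * spec.container_thickness_mm)
    if spec.context_amplitude > 0:
        sigma_px = spec.context_scale_mm / spec.pixel_size_mm
        blobs = ndimage.gaussian_filter(rng.standard_normal((ny, nx)), sigma_px)
        lo, hi = blobs.min(), blobs.max()
        if hi > lo:
            tau += spec.context_amplitude * (blobs - lo) / (hi - lo)

    centers: list[tuple[float, float]] = []
    if spec.microstructure in ("none", "agar_gaps"):
        mask = np.ones((ny, nx), dtype=bool)
    elif spec.microstructure == "vessel":
        X, Y = _pixel_grid_mm(spec)
        y0 = spec.vessel_center_frac * spec.field_of_view_mm[1]
        half = spec.vessel_diameter_um / 2000.0
        mask = np.abs(Y - y0) <= half
    else:  # alveolar: hexagonal packing of equal circular compartments
        X, Y = _pixel_grid_mm(spec)
        r = spec.alveolus_radius_um / 1000.0
        centers = _hex_centers(spec.field_of_view_mm, r)
        mask = np.zeros((ny, nx), dtype=bool)
        for cx, cy in centers:
            mask |= (X - cx) ** 2 + (Y - cy) ** 2 <= r**2
    return Phantom(spec=spec, tau_bg=tau, mask=mask, compartment_centers=centers)


#: centre spacing of alveolar compartments as a fraction of the diameter.
#: Septal walls are thin relative to the compartment radius, so adjacent
#: gas-filled compartments overlap slightly in projection and a bubble
#: spanning them segments as one connected silhouette.
ALVEOLAR_SPACING = 0.95


def _hex_centers(fov_mm: tuple[float, float], r: float) -> list[tuple[float, float]]:
    """Centres of near-touching disks of radius ``r`` hex-packed into the FOV."""
    w, h = fov_mm
    dx, dy = 2 * r * ALVEOLAR_SPACING, math.sqrt(3) * r * ALVEOLAR_SPACING
    centers = []
    row = 0
    cy = r
    while cy <= h - r + 1e-12:
        offset = r if row % 2 else 0.0
        cx = r + offset
        while cx <= w - r + 1e-12:
            centers.append((cx, cy))
            cx += dx
        cy += dy
        row += 1
    return centers


# ---------------------------------------------------------------------------
# Bubble evolution
# ---------------------------------------------------------------------------


@dataclass
class BubbleState:
    """Analytic silhouette of one bubble in one frame.

    ``spheres`` lists (cx, cy, r) disks/spheres; for the vessel law,
    ``capsule`` holds (cx, cy, r, half_length) instead.
    """

    bubble_id: int
    spheres: list[tuple[float, float, float]] = field(default_factory=list)
    capsule: tuple[float, float, float, float] | None = None

    # --- analytic silhouette descriptors -----------------------------------
    def area_mm2(self) -> float:
        if self.capsule is not None:
            _, _, r, hl = self.capsule
            return math.pi * r**2 + 4 * r * hl
        return sum(math.pi * r**2 for _, _, r in self.spheres)

    def perimeter_mm(self) -> float:
        if self.capsule is not None:
            _, _, r, hl = self.capsule
            return 2 * math.pi * r + 4 * hl
        return sum(2 * math.pi * r for _, _, r in self.spheres)

    def volume_mm3(self) -> float:
        if self.capsule is not None:
            _, _, r, hl = self.capsule
            return (4.0 / 3.0) * math.pi * r**3 + 2 * math.pi * r**2 * hl
        return sum((4.0 / 3.0) * math.pi * r**3 for _, _, r in self.spheres)

    def top_mm(self) -> float:
        """Smallest y coordinate of the silhouette; y grows downward, so
        the bubble starts crossing the top edge once this is negative."""
        if self.capsule is not None:
            cx, cy, r, hl = self.capsule
            return cy - r
        return min(cy - r for _, cy, r in self.spheres)

    def bottom_mm(self) -> float:
        """Largest y coordinate of the silhouette; the bubble has fully
        left through the top once this is negative."""
        if self.capsule is not None:
            cx, cy, r, hl = self.capsule
            return cy + r
        return max(cy + r for _, cy, r in self.spheres)

    def path_length(self, X: np.ndarray, Y: np.ndarray) -> np.ndarray:
        """Beam path length through gas (mm) at each pixel centre."""
        t = np.zeros_like(X)
        if self.capsule is not None:
            cx, cy, r, hl = self.capsule
            dy2 = (Y - cy) ** 2
            # cylindrical body
            body = (np.abs(X - cx) <= hl) & (dy2 <= r**2)
            t[body] = 2.0 * np.sqrt(np.maximum(r**2 - dy2[body], 0.0))
            # hemispherical caps
            for sx in (cx - hl, cx + hl):
                d2 = (X - sx) ** 2 + dy2
                cap = (~body) & (d2 <= r**2)
                t[cap] = np.maximum(t[cap], 2.0 * np.sqrt(np.maximum(r**2 - d2[cap], 0.0)))
            return t
        for cx, cy, r in self.spheres:
            d2 = (X - cx) ** 2 + (Y - cy) ** 2
            inside = d2 <= r**2
            t[inside] += 2.0 * np.sqrt(np.maximum(r**2 - d2[inside], 0.0))
        return t


@dataclass
class GroundTruthLedger:
    """Everything the analysis is supposed to recover, per frame and bubble.

    ``per_bubble`` columns: frame, time_s, bubble_id, volume_mm3 (analytic,
    whole bubble), area_mm2, perimeter_mm, in_field.
    ``totals`` columns: frame, time_s, v_infield_mm3 (projected, restricted
    to the field of view), v_cumulative_mm3 (in-field + frozen exited).
    """

    per_bubble: pd.DataFrame
    totals: pd.DataFrame
    exits: list[tuple[int, float, float]]  # (bubble_id, time, frozen volume)
    onset_time: float
    clipped_events: int = 0


def _bubble_state(
    seed_: BubbleSeed, t: float, phantom: Phantom | None
) -> BubbleState | None:
    """Analytic geometry of one bubble at absolute time ``t`` (None before
    nucleation or when the silhouette is degenerate)."""
    t_abo = t - seed_.nucleation_time
    if t_abo <= 0:
        return None
    p = seed_.law_parameters
    x0, y0 = seed_.site
    if seed_.rise_speed_mm_s > 0:
        start = seed_.rise_start if seed_.rise_start is not None else seed_.nucleation_time
        y0 = y0 - seed_.rise_speed_mm_s * max(0.0, t - start)
    if seed_.growth_law == "diffusion":
        r = p.get("growth_rate", 0.05) * math.sqrt(t_abo)
        if r <= 0:
            return None
        return BubbleState(seed_.bubble_id, spheres=[(x0, y0, r)])
    if seed_.growth_law == "vessel_bidirectional":
        r = p.get("radius_mm", 0.05)
        hl = 0.5 * p.get("elongation_rate", 0.02) * t_abo
        return BubbleState(seed_.bubble_id, capsule=(x0, y0, r, hl))
    # alveolar_stepped: compartments fill sequentially.  A filling
    # compartment grows from the septal opening it is invaded through, so
    # its partial sphere stays attached to the previous compartment and
    # the projected silhouette remains one connected component.
    r = p.get("radius_mm", 0.125)
    n = int(p.get("n_compartments", 3))
    dwell = p.get("dwell_s", 8.0)
    fill = p.get("fill_s", 2.0)
    period = dwell + fill
    spheres: list[tuple[float, float, float]] = []
    prev = _compartment_center(x0, y0, 0, r, phantom)
    for k in range(n):
        start_k = k * period
        if t_abo <= start_k:
            break
        frac = min(1.0, (t_abo - start_k) / fill)
        rk = r * frac ** (1.0 / 3.0)
        ck = _compartment_center(x0, y0, k, r, phantom)
        if k > 0 and frac < 1.0:
            # slide the partial sphere out from the previous compartment
            dx, dy = ck[0] - prev[0], ck[1] - prev[1]
            dist = math.hypot(dx, dy)
            if dist > 0:
                pull = (r - rk) / dist
                ck = (ck[0] - dx * pull, ck[1] - dy * pull)
        spheres.append((ck[0], ck[1], rk))
        prev = _compartment_center(x0, y0, k, r, phantom)
    if not spheres:
        return None
    return BubbleState(seed_.bubble_id, spheres=spheres)


def _compartment_center(
    x0: float, y0: float, k: int, r: float, phantom: Phantom | None
) -> tuple[float, float]:
    """k-th compartment of an alveolar bubble: nearest hex cells if the
    phantom carries a packing, otherwise a row of touching disks."""
    if phantom is not None and phantom.compartment_centers:
        centers = sorted(
            phantom.compartment_centers,
            key=lambda c: (c[0] - x0) ** 2 + (c[1] - y0) ** 2,
        )
        if k < len(centers):
            return centers[k]
        k = k - len(centers)  # fall through past the packing edge
    return (x0 + 2 * r * ALVEOLAR_SPACING * k, y0)


def evolve_bubbles(
    seeds: Sequence[BubbleSeed],
    times: np.ndarray,
    phantom: Phantom | None = None,
    spec: PhantomSpec | None = None,
) -> tuple[list[list[BubbleState]], GroundTruthLedger]:
    """Evolve bubble geometry over the sampled time axis.

    Returns per-frame lists of bubble silhouettes plus the ground-truth
    ledger.  A bubble's volume is frozen at its last fully-visible value
    the moment its silhouette starts crossing the top edge of the field
    of view (what an observer can ever measure); from then on the frozen
    value feeds the cumulative total, and once the silhouette has fully
    left, the bubble is retired as an exit event.  Geometry poking
    outside its confining microstructure mask is clipped at render time
    and counted here.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if spec is None and phantom is not None:
        spec = phantom.spec

    crossing: dict[int, float] = {}  # id -> frozen volume while leaving
    exited: dict[int, tuple[float, float]] = {}  # id -> (time, frozen volume)
    frames: list[list[BubbleState]] = []
    rows = []
    totals = []
    clipped = 0
    grid = _pixel_grid_mm(spec) if spec is not None else None

    for fi, t in enumerate(times):
        states: list[BubbleState] = []
        v_cum = 0.0
        for sd in seeds:
            if sd.bubble_id in exited:
                continue
            st = _bubble_state(sd, t, phantom)
            if st is None:
                continue
            if sd.bubble_id not in crossing and st.top_mm() < 0:
                prev = _bubble_state(sd, times[fi - 1], phantom) if fi else None
                crossing[sd.bubble_id] = (
                    prev.volume_mm3() if prev is not None else st.volume_mm3()
                )
            if sd.bubble_id in crossing:
                if st.bottom_mm() < 0:  # fully out: exit event
                    exited[sd.bubble_id] = (t, crossing.pop(sd.bubble_id))
                    continue  # counted via the exited sum below
                v_cum += crossing[sd.bubble_id]
            else:
                v_cum += st.volume_mm3()
            states.append(st)
        frames.append(states)

        v_infield = 0.0
        for st in states:
            if grid is not None:
                pl = st.path_length(*grid)
                if phantom is not None and not phantom.mask.all():
                    outside = (pl > 0) & ~phantom.mask
                    if outside.any():
                        clipped += int(outside.sum())
                        pl = np.where(phantom.mask, pl, 0.0)
                v_in = float(pl.sum()) * spec.pixel_size_mm**2
            else:
                v_in = st.volume_mm3()
            v_infield += v_in
            rows.append(
                {
                    "frame": fi,
                    "time_s": t,
                    "bubble_id": st.bubble_id,
                    "volume_mm3": st.volume_mm3(),
                    "area_mm2": st.area_mm2(),
                    "perimeter_mm": st.perimeter_mm(),
                    "in_field": True,
                }
            )
        v_cum += sum(v for _, v in exited.values())
        totals.append(
            {
                "frame": fi,
                "time_s": t,
                "v_infield_mm3": v_infield,
                "v_cumulative_mm3": v_cum,
            }
        )

    ledger = GroundTruthLedger(
        per_bubble=pd.DataFrame(
            rows,
            columns=[
                "frame",
                "time_s",
                "bubble_id",
                "volume_mm3",
                "area_mm2",
                "perimeter_mm",
                "in_field",
            ],
        ),
        totals=pd.DataFrame(totals),
        exits=[(bid, te, v) for bid, (te, v) in sorted(exited.items())],
        onset_time=min((s.nucleation_time for s in seeds), default=math.nan),
        clipped_events=clipped,
    )
    return frames, ledger


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _flat_profile(spec: PhantomSpec) -> np.ndarray:
    """Smooth beam profile: mild horizontal gradient plus vignetting."""
    ny, nx = spec.shape
    yy = (np.arange(ny)[:, None] - ny / 2) / max(ny, 1)
    xx = (np.arange(nx)[None, :] - nx / 2) / max(nx, 1)
    return spec.photon_scale * (1.0 + 0.04 * xx - 0.05 * (xx**2 + yy**2))


def _drift_mode(spec: PhantomSpec) -> np.ndarray:
    ny, nx = spec.shape
    xx = np.arange(nx)[None, :] / max(nx - 1, 1)
    yy = np.arange(ny)[:, None] / max(ny - 1, 1)
    return np.sin(math.pi * xx) * (0.5 + 0.5 * yy)


def render_stack(
    phantom: Phantom,
    frames_geometry: list[list[BubbleState]],
    times: np.ndarray | None = None,
    seed: int | None = None,
) -> RadiographStack:
    """Render the radiograph sequence plus flat and dark fields.

    Identical seed (and spec) gives a bit-identical stack.  Negative
    intensities produced by noise are clipped at zero and counted in
    ``stack.meta['n_clipped']``.
    """
    spec = phantom.spec
    times = spec.times() if times is None else np.asarray(times, dtype=float)
    if len(times) != len(frames_geometry):
        raise ValueError("times and frame geometry lengths differ")
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    X, Y = _pixel_grid_mm(spec)
    flat0 = _flat_profile(spec)
    mode = _drift_mode(spec)
    t_end = times[-1] if len(times) else 1.0

    def illum(t: float) -> np.ndarray:
        if spec.flat_drift <= 0:
            return flat0
        return flat0 * (1.0 + spec.flat_drift * math.sin(2 * math.pi * t / max(t_end, 1e-9)) * mode)

    frames = np.empty((len(times), *spec.shape), dtype=float)
    n_clipped = 0
    for fi, (t, states) in enumerate(zip(times, frames_geometry)):
        t_gas = np.zeros(spec.shape)
        for st in states:
            pl = st.path_length(X, Y)
            if not phantom.mask.all():
                pl = np.where(phantom.mask, pl, 0.0)
            t_gas += pl
        intensity = illum(t) * np.exp(-phantom.tau_bg + spec.mu_liq_mm * t_gas)
        if spec.fringe_strength > 0:
            intensity += spec.fringe_strength * illum(t) * ndimage.laplace(t_gas)
        intensity += spec.dark_level
        if spec.noise_rel > 0:
            intensity += rng.normal(0.0, spec.noise_rel * np.abs(intensity))
        neg = intensity < 0
        n_clipped += int(neg.sum())
        frames[fi] = np.where(neg, 0.0, intensity)

    # flats sample the illumination over the run (with noise if configured)
    flat_times = np.linspace(0.0, t_end, spec.n_flats)
    flats = np.stack([illum(ft) for ft in flat_times])
    if spec.noise_rel > 0:
        flats = flats + rng.normal(0.0, spec.noise_rel * flats)
    darks = (
        np.full((spec.n_darks, *spec.shape), spec.dark_level)
        if spec.n_darks
        else np.zeros((0, *spec.shape))
    )
    return RadiographStack(
        frames=frames,
        times=times.copy(),
        pixel_size_um=spec.pixel_size_um,
        flats=flats,
        darks=darks,
        meta={"n_clipped": n_clipped, "dark_level": spec.dark_level},
    )


# ---------------------------------------------------------------------------
# Chromatogram rendering
# ---------------------------------------------------------------------------

#: which species elute on which detection module.  The molecular-sieve
#: column (MS5A) separates the fixed gases; the PDMS10 column carries the
#: solvent vapours plus one combined air peak.
MODULE_SPECIES = {
    "MS5A": ("N2", "O2"),
    "PDMS10": ("N2+O2", "H2O", "EtOH"),
}


def render_chromatograms(schedule: GasSchedule, seed: int = 0) -> list[Chromatogram]:
    """Per-cycle chromatograms for the MS5A and PDMS10 modules.

    Each cycle holds Gaussian peaks at the reference retention times with
    areas proportional to the injected amounts, a slowly drifting linear
    baseline, and additive noise.
    """
    rng = np.random.default_rng(seed)
    rt = np.arange(0.0, schedule.rt_max_s + schedule.rt_step_s / 2, schedule.rt_step_s)
    out: list[Chromatogram] = []
    for ci, ct in enumerate(schedule.cycle_times()):
        amounts = schedule.amounts(ct)
        amounts["N2+O2"] = amounts.get("N2", 0.0) + amounts.get("O2", 0.0)
        for module, species in MODULE_SPECIES.items():
            refs = schedule.retention_s[module]
            signal = schedule.baseline_level + schedule.baseline_drift * (
                rt / schedule.rt_max_s
            ) * math.sin(0.7 * ci + 1.0)
            for sp in species:
                area = amounts.get(sp, 0.0)
                if area <= 0:
                    continue
                s = schedule.peak_width_s
                amp = area / (s * math.sqrt(2 * math.pi))
                signal = signal + amp * np.exp(-0.5 * ((rt - refs[sp]) / s) ** 2)
            if schedule.noise_sigma > 0:
                signal = signal + rng.normal(0.0, schedule.noise_sigma, rt.shape)
            out.append(
                Chromatogram(
                    module=module,
                    cycle_index=ci,
                    cycle_time_s=float(ct),
                    retention_time_s=rt.copy(),
                    signal=np.asarray(signal, dtype=float),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Presets: the study conditions, packaged
# ---------------------------------------------------------------------------


def degassed_volume_preset(
    seed: int = 0,
    alpha: float = 3.0,
    k: float = 1.0e-4,
    t_bo: float = 120.0,
    duration_s: float = 840.0,
    frame_rate_hz: float = 3.0,
    noise_rel: float = 0.02,
) -> dict:
    """Cumulative-volume series of a highly degassed sample.

    After a quiescent pre-onset period the cumulative gas volume follows
    ``V_C = k * (t - t_bo)**alpha`` (the consensus cubic growth of highly
    degassed samples) with multiplicative Gaussian noise.  ``k`` is chosen
    so roughly 2e2 mm^3 of gas accumulates over the 10 minutes after
    onset, the scale of a real run.
    """
    rng = np.random.default_rng(seed)
    times = np.arange(int(round(duration_s * frame_rate_hz))) / frame_rate_hz
    t_abo = np.maximum(times - t_bo, 0.0)
    v_true = k * t_abo**alpha
    v_noisy = v_true * (1.0 + noise_rel * rng.standard_normal(times.shape))
    v_noisy = np.maximum(v_noisy, 0.0)
    return {
        "times": times,
        "v_c": v_noisy,
        "truth": {"alpha": alpha, "k": k, "t_bo": t_bo},
    }


def scenario_preset(
    scenario: Literal["diffusion", "vessel", "alveolar"],
    seed: int = 0,
    noise_tau: float = 3.0e-4,
    duration_s: float = 60.0,
) -> dict:
    """Excess-optical-depth movie of one constrained-growth scenario.

    Returns ``dtau`` frames (already context-subtracted, with additive
    Gaussian optical-depth noise), the time base, the pixel size and the
    generating seed/ledger — the direct input to segmentation/tracking.

    The vessel scenario uses a 200 um tube (8 px across at the 25 um pixel
    size): the representative scale of a resolvable tissue vessel while
    keeping the stadium silhouette wide enough for stable shape metrics.
    """
    fov = (10.0, 4.0)
    spec = PhantomSpec(
        field_of_view_mm=fov,
        duration_s=duration_s,
        microstructure={"diffusion": "agar_gaps", "vessel": "vessel", "alveolar": "alveolar"}[
            scenario
        ],
        vessel_diameter_um=200.0,
        alveolus_radius_um=125.0,
        context_amplitude=0.0,
        seed=seed,
    )
    if scenario == "diffusion":
        seeds = [
            BubbleSeed(2.0, (5.0, 2.0), "diffusion", {"growth_rate": 0.06}, bubble_id=1)
        ]
    elif scenario == "vessel":
        seeds = [
            BubbleSeed(
                2.0,
                (5.0, 2.0),
                "vessel_bidirectional",
                {"radius_mm": 0.1, "elongation_rate": 0.03},
                bubble_id=1,
            )
        ]
    else:
        seeds = [
            BubbleSeed(
                2.0,
                (5.0, 2.0),
                "alveolar_stepped",
                {"radius_mm": 0.125, "n_compartments": 4, "dwell_s": 10.0, "fill_s": 2.0},
                bubble_id=1,
            )
        ]
    phantom = build_phantom(spec)
    times = spec.times()
    geoms, ledger = evolve_bubbles(seeds, times, phantom=phantom, spec=spec)
    rng = np.random.default_rng(seed + 1)
    X, Y = _pixel_grid_mm(spec)
    dtau = np.empty((len(times), *spec.shape))
    for fi, states in enumerate(geoms):
        t_gas = np.zeros(spec.shape)
        for st in states:
            pl = st.path_length(X, Y)
            if not phantom.mask.all():
                pl = np.where(phantom.mask, pl, 0.0)
            t_gas += pl
        frame = spec.mu_liq_mm * t_gas
        if noise_tau > 0:
            frame = frame + rng.normal(0.0, noise_tau, spec.shape)
        dtau[fi] = frame
    return {
        "dtau": dtau,
        "times": times,
        "pixel_size_um": spec.pixel_size_um,
        "noise_tau": noise_tau,
        "ledger": ledger,
        "spec": spec,
        "seeds": seeds,
    }


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_simulation(
    out_dir,
    stack: RadiographStack,
    ledger: GroundTruthLedger,
    chromatograms: Sequence[Chromatogram] = (),
) -> dict:
    """Write a simulated run to disk in the package's exchange formats.

    Multi-page 16-bit TIFFs for frames/flats/darks, a timestamps CSV, the
    ground-truth CSVs, and a long-format chromatogram CSV.  Returns the
    paths written.
    """
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    peak = max(float(stack.frames.max()), float(stack.flats.max()), 1.0)
    scale = min(1.0, 60000.0 / peak)
    if scale < 1.0:
        warnings.warn("intensities rescaled to fit 16-bit output")

    def to_u16(a: np.ndarray) -> np.ndarray:
        return np.clip(np.round(a * scale), 0, 65535).astype(np.uint16)

    paths = {
        "frames": out / "frames.tif",
        "flats": out / "flats.tif",
        "darks": out / "darks.tif",
        "timestamps": out / "timestamps.csv",
        "ground_truth_bubbles": out / "ground_truth_bubbles.csv",
        "ground_truth_totals": out / "ground_truth_totals.csv",
    }
    tifffile.imwrite(paths["frames"], to_u16(stack.frames))
    tifffile.imwrite(paths["flats"], to_u16(stack.flats))
    if len(stack.darks):
        tifffile.imwrite(paths["darks"], to_u16(stack.darks))
    else:
        paths.pop("darks")
    pd.DataFrame(
        {"frame_index": np.arange(len(stack.times)), "time_s": stack.times}
    ).to_csv(paths["timestamps"], index=False)
    ledger.per_bubble.to_csv(paths["ground_truth_bubbles"], index=False)
    ledger.totals.to_csv(paths["ground_truth_totals"], index=False)
    if chromatograms:
        rows = []
        for ch in chromatograms:
            for rt, s in zip(ch.retention_time_s, ch.signal):
                rows.append(
                    {
                        "cycle_index": ch.cycle_index,
                        "module": ch.module,
                        "cycle_time_s": ch.cycle_time_s,
                        "retention_time_s": rt,
                        "signal": s,
                    }
                )
        paths["chromatograms"] = out / "chromatograms.csv"
        pd.DataFrame(rows).to_csv(paths["chromatograms"], index=False)
    return paths
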