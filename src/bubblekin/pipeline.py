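"""End-to-end orchestration: simulate/ingest -> correct -> segment ->
volumetry -> kinetics -> GC -> dosimetry -> tabular report.

A run is described by a :class:`RunConfig` holding either a phantom
specification (synthetic run) or paths to measured inputs, plus the
analysis parameters.  ``run`` executes every stage, writes CSV tables and
a JSON manifest under the output directory, and returns the in-memory
:class:`RunReport`.  Reports are deterministic for a given config + seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import gc_analysis, phantom, radio_io, segmentation, volumetry
from .attenuation import MU_LIQ_MM, WORKING_ENERGY_KEV, AttenuationModel
from .dosimetry import DEFAULT_DOSE_RATE_GY_S, DoseProfile
from .kinetics import DEFAULT_FIT_DURATION_S, fit_power_law

logger = logging.getLogger("bubblekin")

__version__ = "0.1.0"


class InputPaths(BaseModel):
    """Measured-data inputs for one sample."""

    stack_dir: str
    timestamps: str | None = None
    chromatograms: str | None = None
    pixel_size_um: float = Field(25.0, gt=0)


class PhantomRun(BaseModel):
    """Synthetic inputs: a phantom spec plus its bubble seeds."""

    spec: dict = Field(default_factory=dict)
    bubbles: list[dict] = Field(default_factory=list)
    gas_schedule: dict | None = None


class RunConfig(BaseModel):
    """Everything one pipeline run needs; exactly one input source."""

    name: str = "run"
    inputs: InputPaths | None = None
    phantom: PhantomRun | None = None
    mu_liq_mm: float = Field(MU_LIQ_MM, gt=0)
    energy_kev: float = WORKING_ENERGY_KEV
    onset_threshold_mm3: float = Field(volumetry.DEFAULT_ONSET_THRESHOLD_MM3, gt=0)
    onset_persistence: int = Field(3, ge=1)
    fit_duration_s: float = Field(DEFAULT_FIT_DURATION_S, gt=0)
    flat_method: str = "static"
    context_window_s: tuple[float, float] | None = None
    gc_reference_rt: dict[str, dict[str, float]] | None = None
    gc_cycle_period_s: float = Field(gc_analysis.DEFAULT_CYCLE_PERIOD_S, gt=0)
    dose_rate_gy_s: float = Field(DEFAULT_DOSE_RATE_GY_S, ge=0)
    output_dir: str = "bubblekin_out"
    seed: int = 0
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _one_source(self) -> "RunConfig":
        if (self.inputs is None) == (self.phantom is None):
            raise ValueError("exactly one of 'inputs' or 'phantom' must be supplied")
        if self.inputs is not None:
            p = Path(self.inputs.stack_dir)
            if not p.exists():
                raise FileNotFoundError(f"stack directory not found: {p}")
        return self

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


@dataclass
class RunReport:
    """Tabular outcome of one pipeline run."""

    onset_table: pd.DataFrame
    growth_table: pd.DataFrame
    classification_table: pd.DataFrame
    gc_summary: pd.DataFrame
    volume_series: volumetry.VolumeSeries | None
    provenance: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> dict[str, str]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, df in [
            ("onset", self.onset_table),
            ("growth_fits", self.growth_table),
            ("classifications", self.classification_table),
            ("gc_summary", self.gc_summary),
        ]:
            p = out / f"{name}.csv"
            df.to_csv(p, index=False)
            paths[name] = str(p)
        if self.volume_series is not None:
            vs = self.volume_series
            df = pd.DataFrame({"time_s": vs.times, "v_mm3": vs.v})
            if vs.v_c is not None:
                df["v_c_mm3"] = vs.v_c
            p = out / "volume_series.csv"
            df.to_csv(p, index=False)
            paths["volume_series"] = str(p)
        manifest = out / "manifest.json"
        with open(manifest, "w") as fh:
            json.dump(self.provenance, fh, indent=2, sort_keys=True)
        paths["manifest"] = str(manifest)
        return paths


def _load_inputs(config: RunConfig):
    """Produce (stack, chromatograms, truth_onset) from either source."""
    if config.phantom is not None:
        spec = phantom.PhantomSpec(**{"seed": config.seed, **config.phantom.spec})
        ph = phantom.build_phantom(spec)
        seeds = [phantom.BubbleSeed(**b) for b in config.phantom.bubbles]
        times = spec.times()
        geoms, ledger = phantom.evolve_bubbles(seeds, times, phantom=ph, spec=spec)
        stack = phantom.render_stack(ph, geoms, times)
        chroms = []
        if config.phantom.gas_schedule is not None:
            sched = phantom.GasSchedule(**config.phantom.gas_schedule)
            chroms = phantom.render_chromatograms(sched, seed=config.seed)
        return stack, chroms, ledger
    stack = radio_io.read_stack(
        config.inputs.stack_dir,
        config.inputs.timestamps,
        pixel_size_um=config.inputs.pixel_size_um,
    )
    chroms = (
        gc_analysis.read_chromatograms(config.inputs.chromatograms)
        if config.inputs.chromatograms
        else []
    )
    return stack, chroms, None


def run(config: RunConfig) -> RunReport:
    """Execute the full pipeline for one configuration."""
    logging.basicConfig(level=config.log_level)
    logger.info(
        "run %s: mu_liq=%.5f mm^-1, onset threshold=%.3e mm^3, "
        "persistence=%d frames, fit window=%.0f s, dose rate=%.1f Gy/s",
        config.name,
        config.mu_liq_mm,
        config.onset_threshold_mm3,
        config.onset_persistence,
        config.fit_duration_s,
        config.dose_rate_gy_s,
    )
    model = AttenuationModel(mu_liq=config.mu_liq_mm, energy_kev=config.energy_kev)
    stack, chroms, ledger = _load_inputs(config)

    # --- transmission and context -----------------------------------------
    corr = radio_io.flat_field_correct(stack, method=config.flat_method)
    window = config.context_window_s
    if window is None:
        # default: the first sixth of the run, at least 5 frames
        n_pre = max(5, len(stack.times) // 6)
        window = (float(stack.times[0]), float(stack.times[n_pre - 1]))
    context = radio_io.build_context(corr.transmission, stack.times, window, mask=corr.mask)
    noise_sigma = radio_io.estimate_noise_sigma(
        corr.transmission[: max(5, len(stack.times) // 6)], context, corr.mask
    )
    logger.info("estimated optical-depth noise sigma = %.4g", noise_sigma)

    # --- volumetry and onset ----------------------------------------------
    series = volumetry.volume_series(
        corr.transmission,
        stack.times,
        context,
        model,
        stack.pixel_size_um,
        noise_sigma=noise_sigma,
        mask=corr.mask,
    )
    onset = volumetry.detect_onset(
        stack.times,
        series.v,
        threshold_volume=config.onset_threshold_mm3,
        persistence=config.onset_persistence,
    )

    # --- segmentation and tracking ----------------------------------------
    floor = 3.0 * noise_sigma
    smooth_px = 1.0 if noise_sigma > 0 else 0.0
    dtau_frames = np.empty_like(corr.transmission)
    for i in range(len(stack.times)):
        tau = radio_io.optical_depth(corr.transmission[i], corr.mask)
        dtau_frames[i], _ = radio_io.excess_depth(
            tau, context, noise_floor=floor, smooth_px=smooth_px
        )
    labels, meas = segmentation.segment_stack(
        dtau_frames, stack.times, stack.pixel_size_um
    )
    tracks = segmentation.track_bubbles(
        labels, meas, stack.times, pixel_size_um=stack.pixel_size_um
    )
    exits = volumetry.exits_from_tracks(tracks, model, stack.pixel_size_um)
    series = volumetry.accumulate(series, exits, onset)

    # --- dosimetry ----------------------------------------------------------
    dose = DoseProfile(dose_rate=config.dose_rate_gy_s, t_ron=float(stack.times[0]))
    onset_rows = [
        {
            "sample": config.name,
            "t_bo_s": onset.t_bo,
            "t_bbo_s": onset.t_bbo,
            "detected": onset.detected,
            "d_at_onset_gy": dose.mark_onset(onset.t_bo) if onset.detected else np.nan,
            "true_t_bo_s": ledger.onset_time if ledger is not None else np.nan,
        }
    ]

    # --- kinetics -----------------------------------------------------------
    growth_rows = []
    if onset.detected:
        try:
            fit = fit_power_law(
                stack.times, series.v_c, onset.t_bo, fit_duration=config.fit_duration_s
            )
            growth_rows.append(
                {
                    "sample": config.name,
                    "alpha": fit.alpha,
                    "alpha_se": fit.alpha_se,
                    "k": fit.k,
                    "method": fit.method,
                    "n_points": fit.n_points,
                }
            )
        except ValueError as err:
            logger.warning("growth fit skipped: %s", err)

    # --- per-track classification -------------------------------------------
    cls_rows = []
    for tr in tracks:
        if len(tr) < 10:
            continue
        cls_rows.append(
            {
                "sample": config.name,
                "track_id": tr.track_id,
                "status": tr.status,
                "n_frames": len(tr),
                "classification": segmentation.classify_growth(tr),
            }
        )

    # --- gas chromatography ---------------------------------------------------
    if chroms:
        conc = gc_analysis.analyse_chromatograms(chroms, config.gc_reference_rt)
        t_bo_for_gc = onset.t_bo if onset.detected else float(stack.times[-1])
        gc_summary = gc_analysis.onset_window_summary(
            conc, t_bo_for_gc, cycle_period_s=config.gc_cycle_period_s
        )
        gc_summary.insert(0, "sample", config.name)
    else:
        gc_summary = pd.DataFrame()

    report = RunReport(
        onset_table=pd.DataFrame(onset_rows),
        growth_table=pd.DataFrame(
            growth_rows, columns=["sample", "alpha", "alpha_se", "k", "method", "n_points"]
        ),
        classification_table=pd.DataFrame(
            cls_rows,
            columns=["sample", "track_id", "status", "n_frames", "classification"],
        ),
        gc_summary=gc_summary,
        volume_series=series,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "software_version": __version__,
            "mu_liq_mm": config.mu_liq_mm,
            "noise_sigma_tau": noise_sigma,
        },
    )
    report.write(config.output_dir)
    return report


def simulate(config: RunConfig) -> dict:
    """Render the configured phantom to disk (no analysis)."""
    if config.phantom is None:
        raise ValueError("simulate requires a phantom configuration")
    stack, chroms, ledger = _load_inputs(config)
    return phantom.write_simulation(config.output_dir, stack, ledger, chroms)


EXPECTED_DEPOSIT = ("X-ray_imaging.zip", "Gaz_chromatography.zip", "Analysis.zip")


def replicate_from_deposit(
    deposit_dir: str | Path,
    mapping_file: str | Path | None = None,
    output_dir: str | Path = "replication_out",
) -> list[RunReport]:
    """Analyse a locally downloaded copy of the study's data deposit.

    The deposit is never fetched automatically.  Its internal layout is
    not standardised, so a user-supplied JSON mapping is required, of the
    form ``{"samples": [{"name", "stack_dir", "timestamps",
    "chromatograms"}]}`` with paths relative to the deposit directory.
    """
    deposit = Path(deposit_dir)
    if not deposit.exists():
        raise FileNotFoundError(
            f"deposit directory not found: {deposit}. Download and extract the "
            f"archives ({', '.join(EXPECTED_DEPOSIT)}) there first."
        )
    if mapping_file is None or not Path(mapping_file).exists():
        raise FileNotFoundError(
            "a mapping file describing the deposit layout is required: JSON with "
            'a "samples" list of {name, stack_dir, timestamps, chromatograms}'
        )
    with open(mapping_file) as fh:
        mapping = json.load(fh)
    samples = mapping.get("samples", [])
    if not samples:
        raise ValueError("mapping file lists no samples")
    reports = []
    for s in samples:
        cfg = RunConfig(
            name=s["name"],
            inputs=InputPaths(
                stack_dir=str(deposit / s["stack_dir"]),
                timestamps=str(deposit / s["timestamps"]) if s.get("timestamps") else None,
                chromatograms=str(deposit / s["chromatograms"])
                if s.get("chromatograms")
                else None,
            ),
            output_dir=str(Path(output_dir) / s["name"]),
        )
        reports.append(run(cfg))
    return reports
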