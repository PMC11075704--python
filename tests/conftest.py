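"""Shared synthetic runs, rendered once per session."""

from __future__ import annotations

import numpy as np
import pytest

from bubblekin import phantom as ph
from bubblekin import radio_io as rio
from bubblekin.attenuation import AttenuationModel


def render_sphere_run(noise_rel: float, seed: int = 3):
    """A single bubble growing to a 1 mm radius sphere at t = 6 s."""
    spec = ph.PhantomSpec(
        field_of_view_mm=(6.0, 4.0),
        duration_s=8.0,
        context_amplitude=0.2,
        noise_rel=noise_rel,
        microstructure="agar_gaps",
        seed=seed,
    )
    p = ph.build_phantom(spec)
    seeds = [
        ph.BubbleSeed(
            4.0, (3.0, 2.0), "diffusion", {"growth_rate": 1.0 / np.sqrt(2.0)}, bubble_id=1
        )
    ]
    times = spec.times()
    geoms, ledger = ph.evolve_bubbles(seeds, times, phantom=p, spec=spec)
    stack = ph.render_stack(p, geoms, times)
    corr = rio.flat_field_correct(stack)
    context = rio.build_context(corr.transmission, times, (0.0, 3.5), mask=corr.mask)
    sigma = rio.estimate_noise_sigma(corr.transmission[times <= 3.5], context, corr.mask)
    return {
        "spec": spec,
        "phantom": p,
        "times": times,
        "geoms": geoms,
        "ledger": ledger,
        "stack": stack,
        "corr": corr,
        "context": context,
        "noise_sigma": sigma,
        "model": AttenuationModel(mu_liq=spec.mu_liq_mm),
    }


@pytest.fixture(scope="session")
def sphere_run():
    return render_sphere_run(0.0)


@pytest.fixture(scope="session")
def sphere_run_noisy():
    return render_sphere_run(0.02)


def render_exit_run():
    """Three bubbles, two of which rise out through the top (exits)."""
    spec = ph.PhantomSpec(
        field_of_view_mm=(10.0, 4.0),
        duration_s=40.0,
        context_amplitude=0.2,
        noise_rel=0.0,
        microstructure="agar_gaps",
        seed=5,
    )
    p = ph.build_phantom(spec)
    seeds = [
        ph.BubbleSeed(6.0, (3.0, 2.5), "diffusion", {"growth_rate": 0.09},
                      rise_speed_mm_s=0.8, rise_start=14.0, bubble_id=1),
        ph.BubbleSeed(10.0, (7.0, 2.0), "diffusion", {"growth_rate": 0.08},
                      rise_speed_mm_s=0.8, rise_start=26.0, bubble_id=2),
        ph.BubbleSeed(8.0, (5.0, 1.8), "diffusion", {"growth_rate": 0.16}, bubble_id=3),
    ]
    times = spec.times()
    geoms, ledger = ph.evolve_bubbles(seeds, times, phantom=p, spec=spec)
    stack = ph.render_stack(p, geoms, times)
    corr = rio.flat_field_correct(stack)
    context = rio.build_context(corr.transmission, times, (0.0, 5.5), mask=corr.mask)
    return {
        "spec": spec,
        "times": times,
        "ledger": ledger,
        "stack": stack,
        "corr": corr,
        "context": context,
        "model": AttenuationModel(mu_liq=spec.mu_liq_mm),
    }


@pytest.fixture(scope="session")
def exit_run():
    return render_exit_run()


@pytest.fixture(scope="session")
def scenario_tracks():
    """Segmented and tracked main bubble per growth scenario (1 seed)."""
    from bubblekin import segmentation as seg

    out = {}
    for scen in ("diffusion", "vessel", "alveolar"):
        d = ph.scenario_preset(scen, seed=0)
        dt = d["dtau"].copy()
        dt[dt < 3 * d["noise_tau"]] = 0.0
        labels, meas = seg.segment_stack(dt, d["times"], d["pixel_size_um"])
        tracks = seg.track_bubbles(labels, meas, d["times"], pixel_size_um=d["pixel_size_um"])
        out[scen] = {"preset": d, "tracks": tracks, "main": max(tracks, key=len)}
    return out
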