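"""Stack I/O, flat-field correction, context subtraction."""

import numpy as np
import pandas as pd
import pytest

from bubblekin import phantom as ph
from bubblekin import radio_io as rio


@pytest.fixture(scope="module")
def written_run(tmp_path_factory):
    """A small simulated run written to disk in the exchange formats."""
    out = tmp_path_factory.mktemp("sim")
    spec = ph.PhantomSpec(field_of_view_mm=(3.0, 1.5), duration_s=60.0,
                          noise_rel=0.0, context_amplitude=0.1, seed=1)
    p = ph.build_phantom(spec)
    sds = [ph.BubbleSeed(30.0, (1.5, 0.75), "diffusion", {"growth_rate": 0.02},
                         bubble_id=1)]
    times = spec.times()
    geoms, led = ph.evolve_bubbles(sds, times, phantom=p, spec=spec)
    stack = ph.render_stack(p, geoms, times)
    paths = ph.write_simulation(out, stack, led)
    return {"dir": out, "paths": paths, "stack": stack, "spec": spec}


class TestReadStack:
    def test_round_trip_preserves_frame_count(self, written_run):
        stack = rio.read_stack(written_run["dir"])
        assert len(stack.frames) == len(written_run["stack"].frames)
        assert np.allclose(stack.times, written_run["stack"].times)

    def test_three_fps_sixty_seconds_is_180_frames(self, written_run):
        stack = rio.read_stack(written_run["dir"])
        assert len(stack.frames) == 180

    def test_missing_timestamp_row_reports_frame_index(self, written_run, tmp_path):
        ts = pd.read_csv(written_run["paths"]["timestamps"])
        bad = tmp_path / "short.csv"
        ts.iloc[:-1].to_csv(bad, index=False)
        with pytest.raises(ValueError, match="179"):
            rio.read_stack(written_run["dir"], timestamps=bad)

    def test_missing_flats_is_explicit(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "frames.tif", np.zeros((2, 4, 4), dtype=np.uint16))
        with pytest.raises(FileNotFoundError, match="flat"):
            rio.read_stack(tmp_path)

    def test_stack_validates_time_base(self):
        with pytest.raises(ValueError, match="increasing"):
            rio.RadiographStack(frames=np.zeros((2, 3, 3)), times=np.array([1.0, 1.0]),
                                pixel_size_um=25.0, flats=np.ones((1, 3, 3)))


class TestFlatFieldCorrect:
    def test_identity_when_frame_equals_flat(self):
        flat = np.full((8, 8), 1000.0)
        stack = rio.RadiographStack(frames=flat[None].repeat(3, axis=0),
                                    times=np.arange(3.0), pixel_size_um=25.0,
                                    flats=flat[None])
        corr = rio.flat_field_correct(stack)
        assert np.allclose(corr.transmission, 1.0)

    def test_noiseless_inversion_recovers_tau_exactly(self, sphere_run):
        # -ln T on the corrected noiseless stack is the generator's optical depth
        run = sphere_run
        tau = rio.optical_depth(run["corr"].transmission[0], run["corr"].mask)
        assert np.allclose(tau, run["phantom"].tau_bg, atol=1e-10)

    def test_dynamic_beats_static_under_illumination_drift(self):
        spec = ph.PhantomSpec(field_of_view_mm=(8.0, 4.0), duration_s=20.0,
                              context_amplitude=0.2, noise_rel=0.0, flat_drift=0.05,
                              n_flats=12, seed=7)
        p = ph.build_phantom(spec)
        sds = [ph.BubbleSeed(5.0, (4.0, 2.0), "diffusion", {"growth_rate": 0.15},
                             bubble_id=1)]
        times = spec.times()
        geoms, _ = ph.evolve_bubbles(sds, times, phantom=p, spec=spec)
        stack = ph.render_stack(p, geoms, times)
        X, Y = ph._pixel_grid_mm(spec)
        t_true = np.empty_like(stack.frames)
        for i, states in enumerate(geoms):
            tg = np.zeros(spec.shape)
            for st in states:
                tg += st.path_length(X, Y)
            t_true[i] = np.exp(-p.tau_bg + spec.mu_liq_mm * tg)
        res = {
            m: np.linalg.norm(rio.flat_field_correct(stack, method=m).transmission - t_true)
            for m in ("static", "dynamic")
        }
        assert res["dynamic"] < res["static"]

    def test_requires_a_flat(self):
        stack = rio.RadiographStack(frames=np.ones((1, 3, 3)), times=np.array([0.0]),
                                    pixel_size_um=25.0, flats=np.ones((1, 3, 3)))
        stack.flats = np.zeros((0, 3, 3))
        with pytest.raises(ValueError):
            rio.flat_field_correct(stack)


class TestContextAndExcess:
    def test_constant_frames_give_single_frame_tau(self):
        t = np.full((6, 4, 4), 0.5)
        ctx = rio.build_context(t, np.arange(6.0), (0.0, 5.0))
        assert np.allclose(ctx.tau_ref, -np.log(0.5))
        assert ctx.n_frames_used == 6

    def test_median_lies_within_observed_range(self):
        rng = np.random.default_rng(0)
        t = np.clip(0.5 + 0.02 * rng.standard_normal((11, 5, 5)), 0.01, None)
        ctx = rio.build_context(t, np.arange(11.0), (0.0, 10.0))
        tau = -np.log(t)
        assert (ctx.tau_ref >= tau.min(axis=0) - 1e-12).all()
        assert (ctx.tau_ref <= tau.max(axis=0) + 1e-12).all()

    def test_context_recovers_background_within_noise(self, sphere_run_noisy):
        run = sphere_run_noisy
        n = int((run["times"] <= 3.5).sum())
        tol = 6 * run["spec"].noise_rel / np.sqrt(n)  # generous per-pixel band
        resid = run["context"].tau_ref - run["phantom"].tau_bg
        assert np.quantile(np.abs(resid), 0.99) < tol

    def test_window_overlapping_onset_rejected(self):
        t = np.full((10, 4, 4), 0.5)
        with pytest.raises(ValueError, match="onset"):
            rio.build_context(t, np.arange(10.0), (0.0, 8.0), onset_time=5.0)

    def test_window_too_short_rejected(self):
        t = np.full((10, 4, 4), 0.5)
        with pytest.raises(ValueError, match=">= 5"):
            rio.build_context(t, np.arange(10.0), (0.0, 2.0))

    def test_frame_equal_to_context_gives_zero(self):
        ctx = rio.ContextMap(tau_ref=np.full((4, 4), 1.2), n_frames_used=5)
        dtau, diag = rio.excess_depth(np.full((4, 4), 1.2), ctx)
        assert np.allclose(dtau, 0.0)
        assert diag["n_negative_clipped"] == 0

    def test_gas_path_product_oracle(self):
        # 2 mm of gas at mu = 0.018 / mm displaces 0.036 of optical depth
        mu = 0.018
        ctx = rio.ContextMap(tau_ref=np.full((4, 4), 1.26), n_frames_used=5)
        tau = np.full((4, 4), 1.26)
        tau[2, 2] -= mu * 2.0
        dtau, _ = rio.excess_depth(tau, ctx)
        assert dtau[2, 2] == pytest.approx(0.036)

    def test_negative_excursions_clipped_and_counted(self):
        ctx = rio.ContextMap(tau_ref=np.full((4, 4), 1.0), n_frames_used=5)
        tau = np.full((4, 4), 1.0)
        tau[0, 0] = 1.5  # denser than reference
        dtau, diag = rio.excess_depth(tau, ctx)
        assert dtau[0, 0] == 0.0
        assert diag["n_negative_clipped"] == 1

    def test_full_chain_recovers_gas_path_exactly(self, sphere_run):
        # flat-field -> -ln -> context subtraction on a noiseless stack
        # returns mu_liq * t_gas for every frame, with no NaN anywhere
        run = sphere_run
        X, Y = ph._pixel_grid_mm(run["spec"])
        i = len(run["times"]) - 1
        t_gas = np.zeros(run["spec"].shape)
        for st in run["geoms"][i]:
            t_gas += st.path_length(X, Y)
        tau = rio.optical_depth(run["corr"].transmission[i], run["corr"].mask)
        dtau, _ = rio.excess_depth(tau, run["context"])
        assert np.isfinite(dtau).all()
        assert np.allclose(dtau, run["spec"].mu_liq_mm * t_gas, atol=1e-9)

    def test_depth_map_writer_round_trip(self, tmp_path):
        import tifffile

        dtau = np.random.default_rng(1).random((3, 4, 4)).astype(np.float32)
        rio.write_depth_maps(tmp_path / "dtau.tif", dtau, {"noise_floor": 0.01})
        back = tifffile.imread(tmp_path / "dtau.tif")
        assert np.allclose(back, dtau)
        assert (tmp_path / "dtau.json").exists()
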