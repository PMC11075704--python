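"""Synthetic phantom: geometry, growth laws, rendering, ground truth."""

import math

import numpy as np
import pytest
from scipy import stats

from bubblekin import phantom as ph


class TestSpecValidation:
    def test_defaults_match_acquisition_geometry(self):
        spec = ph.PhantomSpec()
        assert spec.pixel_size_um == 25.0
        assert spec.frame_rate_hz == 3.0
        assert spec.shape == (160, 2000)  # 4 mm x 50 mm at 25 um

    def test_rejects_nonpositive_lengths(self):
        with pytest.raises(ValueError):
            ph.PhantomSpec(pixel_size_um=0.0)
        with pytest.raises(ValueError):
            ph.PhantomSpec(fringe_strength=-0.1)

    def test_rejects_vessel_wider_than_field(self):
        with pytest.raises(ValueError, match="vessel"):
            ph.PhantomSpec(field_of_view_mm=(10.0, 0.05), microstructure="vessel")

    def test_seed_parameters_must_be_positive(self):
        with pytest.raises(ValueError):
            ph.BubbleSeed(-1.0, (0, 0), "diffusion")
        with pytest.raises(ValueError):
            ph.BubbleSeed(0.0, (0, 0), "diffusion", {"growth_rate": -2.0})


class TestBuildPhantom:
    def test_homogeneous_slab_background(self):
        spec = ph.PhantomSpec(field_of_view_mm=(2.0, 1.0), microstructure="none",
                              context_amplitude=0.0)
        p = ph.build_phantom(spec)
        expected = spec.mu_liq_mm * spec.container_thickness_mm
        assert np.allclose(p.tau_bg, expected)
        assert p.mask.all()

    def test_vessel_mask_width_matches_diameter(self):
        spec = ph.PhantomSpec(field_of_view_mm=(2.0, 1.0), microstructure="vessel",
                              vessel_diameter_um=100.0)
        p = ph.build_phantom(spec)
        widths = p.mask.sum(axis=0)
        assert (widths == 4).all()  # 100 um tube is 4 px at 25 um pixels

    def test_alveolar_packing_area(self):
        spec = ph.PhantomSpec(field_of_view_mm=(4.0, 2.0), microstructure="alveolar",
                              alveolus_radius_um=125.0)
        p = ph.build_phantom(spec)
        n = len(p.compartment_centers)
        assert n > 0
        disk_mm2 = math.pi * 0.125**2
        mask_mm2 = p.mask.sum() * spec.pixel_size_mm**2
        # union of slightly overlapping disks: close to, but below, n * area
        assert 0.88 * n * disk_mm2 < mask_mm2 <= 1.02 * n * disk_mm2


class TestGrowthLaws:
    def test_diffusion_area_doubles_with_time(self):
        sd = ph.BubbleSeed(0.0, (5.0, 5.0), "diffusion", {"growth_rate": 0.1}, bubble_id=1)
        a1 = ph._bubble_state(sd, 3.0, None).area_mm2()
        a2 = ph._bubble_state(sd, 6.0, None).area_mm2()
        assert a2 / a1 == pytest.approx(2.0, rel=1e-12)

    def test_stadium_circularity_closed_form(self):
        # capsule elongated to L = 2r: 4*pi*(pi r^2 + 4 r^2) / (2 pi r + 4 r)^2
        r = 0.1
        sd = ph.BubbleSeed(0.0, (5.0, 5.0), "vessel_bidirectional",
                           {"radius_mm": r, "elongation_rate": 0.05}, bubble_id=1)
        st = ph._bubble_state(sd, (2 * r) / 0.05, None)
        circ = 4 * math.pi * st.area_mm2() / st.perimeter_mm() ** 2
        assert circ == pytest.approx(0.8487, abs=1e-3)

    def test_alveolar_plateaus_match_compartment_areas(self):
        sd = ph.BubbleSeed(0.0, (5.0, 5.0), "alveolar_stepped",
                           {"radius_mm": 0.125, "n_compartments": 3,
                            "dwell_s": 8.0, "fill_s": 1.0}, bubble_id=1)
        t = np.arange(0.1, 27.0, 1.0 / 3.0)
        areas = np.array([ph._bubble_state(sd, ti, None).area_mm2() for ti in t])
        plateau_levels = sorted(set(np.round(areas, 6)))
        disk = math.pi * 0.125**2
        # at least two plateaus separated by jumps of about one compartment
        for k in (1, 2, 3):
            level = k * disk
            assert np.any(np.abs(areas - level) < 0.07 * disk), f"missing plateau {k}"
        jumps = np.diff(np.unique(np.round(areas[areas > disk * 0.99], 8)))
        assert len(plateau_levels) >= 3

    def test_sphere_chord_peaks_at_diameter(self):
        st = ph.BubbleState(1, spheres=[(3.0, 2.0, 1.0)])
        x = np.linspace(0, 6, 601)
        y = np.linspace(0, 4, 401)
        X, Y = np.meshgrid(x, y)
        assert st.path_length(X, Y).max() == pytest.approx(2.0, abs=1e-4)


class TestLedger:
    def test_ledger_volumes_nondecreasing_and_additive(self, exit_run):
        led = exit_run["ledger"]
        vc = led.totals.v_cumulative_mm3.to_numpy()
        assert (np.diff(vc) >= -1e-12).all()
        # per-frame in-field total equals the sum over bubbles when nothing
        # is mid-exit (all analytic volumes fully inside the field)
        assert led.onset_time == 6.0
        assert len(led.exits) == 2

    def test_diffusion_log_area_slope_is_one(self):
        spec = ph.PhantomSpec(field_of_view_mm=(10.0, 4.0), duration_s=40.0,
                              context_amplitude=0.0, seed=0)
        seeds = [ph.BubbleSeed(2.0, (5.0, 2.0), "diffusion", {"growth_rate": 0.05},
                               bubble_id=1)]
        times = spec.times()
        _, led = ph.evolve_bubbles(seeds, times, spec=spec)
        df = led.per_bubble
        t_abo = df.time_s.to_numpy() - 2.0
        good = t_abo > 0
        res = stats.linregress(np.log(t_abo[good]), np.log(df.area_mm2.to_numpy()[good]))
        assert res.slope == pytest.approx(1.0, abs=0.02)

    def test_times_must_increase(self):
        with pytest.raises(ValueError):
            ph.evolve_bubbles([], np.array([0.0, 0.0, 1.0]))


class TestRendering:
    def test_no_bubbles_is_pure_beer_lambert(self):
        spec = ph.PhantomSpec(field_of_view_mm=(3.0, 1.5), duration_s=2.0,
                              context_amplitude=0.15, noise_rel=0.0, seed=2)
        p = ph.build_phantom(spec)
        times = spec.times()
        geoms, _ = ph.evolve_bubbles([], times, phantom=p, spec=spec)
        stack = ph.render_stack(p, geoms, times)
        assert np.allclose(stack.frames[0], stack.flats[0] * np.exp(-p.tau_bg))

    def test_same_seed_bit_identical(self):
        def make():
            spec = ph.PhantomSpec(field_of_view_mm=(3.0, 1.5), duration_s=3.0,
                                  noise_rel=0.02, seed=9)
            p = ph.build_phantom(spec)
            sds = [ph.BubbleSeed(1.0, (1.5, 0.75), "diffusion",
                                 {"growth_rate": 0.1}, bubble_id=1)]
            times = spec.times()
            geoms, _ = ph.evolve_bubbles(sds, times, phantom=p, spec=spec)
            return ph.render_stack(p, geoms, times)

        a, b = make(), make()
        assert np.array_equal(a.frames, b.frames)
        assert np.array_equal(a.flats, b.flats)
        ca = ph.render_chromatograms(ph.GasSchedule(), seed=4)
        cb = ph.render_chromatograms(ph.GasSchedule(), seed=4)
        assert all(np.array_equal(x.signal, y.signal) for x, y in zip(ca, cb))

    def test_transmission_within_noise_bound(self, sphere_run_noisy):
        corr = sphere_run_noisy["corr"]
        sigma = sphere_run_noisy["spec"].noise_rel
        t = corr.transmission[:, corr.mask]
        assert t.min() >= 0.0
        assert t.max() <= 1.0 + 5 * sigma


class TestChromatogramPhantom:
    def test_single_species_single_peak(self):
        sched = ph.GasSchedule(pre_fractions={"EtOH": 1.0}, post_fractions={"EtOH": 1.0},
                               noise_sigma=0.0, baseline_drift=0.0, n_cycles=1)
        chroms = ph.render_chromatograms(sched, seed=0)
        pdms = next(c for c in chroms if c.module == "PDMS10")
        above = pdms.signal > sched.baseline_level + 0.5
        from scipy import ndimage
        _, npk = ndimage.label(above)
        assert npk == 1

    def test_equal_fixed_gas_amounts_give_equal_peaks(self):
        sched = ph.GasSchedule(pre_fractions={"N2": 0.5, "O2": 0.5},
                               post_fractions={"N2": 0.5, "O2": 0.5},
                               noise_sigma=0.0, baseline_drift=0.0, n_cycles=1)
        ms5a = next(c for c in ph.render_chromatograms(sched, 0) if c.module == "MS5A")
        rt, y = ms5a.retention_time_s, ms5a.signal - sched.baseline_level
        n2 = y[np.abs(rt - 35.0) < 10].sum()
        o2 = y[np.abs(rt - 55.0) < 10].sum()
        assert n2 == pytest.approx(o2, rel=1e-6)

    def test_solvent_shift_present_after_onset(self):
        sched = ph.GasSchedule()
        pre = sched.amounts(sched.onset_time_s - 1.0)
        post = sched.amounts(sched.onset_time_s + 1.0)
        assert post["EtOH"] > pre["EtOH"]
        assert post["H2O"] < pre["H2O"]
        assert post["N2"] == pytest.approx(pre["N2"])
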