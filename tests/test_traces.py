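"""Trace processing: registration, extraction, bleach fit, ΔF/F, resampling,
responder/peak statistics."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from flpstop_pipeline import (
    RoiTrace,
    SimConfig,
    StimulusSpec,
    build_stimulus_log,
    compensate_delay,
    compute_dff,
    extract_roi_trace,
    fit_bleach,
    generate_roi_traces,
    identify_responder,
    normalize_peaks,
    peak_response,
    register_frames,
    stimulus_locked_average,
)
from flpstop_pipeline.stimulus import StimulusLog, Transition
from flpstop_pipeline.synthetic import bleach_envelope
from flpstop_pipeline.traces import BleachFit, DffTrace, fitting_mask


def brute_force_stim_locked(dff, log, transition_type, window_s, shift_s, pre_s, post_s):
    """Independent oracle: per-grid-point mean over pooled reassigned samples."""
    trans = [tr.t_s for tr in log.transitions if tr.type == transition_type]
    rel, vals = [], []
    for t0 in trans:
        for t, v in zip(dff.times_s, dff.dff):
            rel.append(t - t0)
            vals.append(v)
    rel = np.asarray(rel)
    vals = np.asarray(vals)
    grid, mean, n = [], [], []
    k = 0
    while -pre_s + k * shift_s <= post_s + 1e-9:
        tk = -pre_s + k * shift_s
        sel = (rel >= tk - window_s / 2) & (rel < tk + window_s / 2)
        if sel.sum() > 0:
            grid.append(tk)
            mean.append(vals[sel].mean())
            n.append(int(sel.sum()))
        k += 1
    return np.asarray(grid), np.asarray(mean), np.asarray(n)


class TestRegisterFrames:
    @staticmethod
    def _base_stack(seed=0, n=12, shape=(48, 40)):
        rng = np.random.default_rng(seed)
        frame = rng.uniform(0, 100, size=shape)
        # smooth a little so correlation has a clean peak
        from scipy.ndimage import gaussian_filter
        frame = gaussian_filter(frame, 2)
        return np.stack([frame] * n)

    def test_aligned_stack_has_zero_shifts(self):
        stack = self._base_stack()
        _, shifts = register_frames(stack)
        np.testing.assert_array_equal(shifts, 0)

    def test_known_translation_recovered_exactly(self):
        stack = self._base_stack()
        stack[5] = np.roll(stack[5], (3, -2), axis=(0, 1))
        aligned, shifts = register_frames(stack)
        assert tuple(shifts[5]) == (-3, 2)
        np.testing.assert_allclose(aligned[5], stack[0])

    def test_noise_frames_shift_bounded_by_max(self):
        rng = np.random.default_rng(1)
        stack = rng.uniform(0, 1, size=(12, 48, 40))
        _, shifts = register_frames(stack, max_shift=4)
        assert np.all(np.abs(shifts) <= 4)

    def test_empty_stack_rejected(self):
        with pytest.raises(ValueError):
            register_frames(np.zeros((1, 8, 8)))


class TestExtractRoiTrace:
    def test_uniform_frame_background_subtraction(self):
        stack = np.full((3, 10, 10), 10.0)
        roi = np.zeros((10, 10), bool)
        roi[4:6, 4:6] = True
        bg = np.zeros((10, 10), bool)
        bg[0:2, 0:2] = True
        stack[:, bg] = 4.0
        tr = extract_roi_trace(stack, roi, bg)
        np.testing.assert_array_equal(tr.F, [6.0, 6.0, 6.0])

    def test_overlapping_masks_rejected(self):
        stack = np.zeros((2, 4, 4))
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError, match="disjoint"):
            extract_roi_trace(stack, m, m)

    def test_empty_mask_rejected(self):
        stack = np.zeros((2, 4, 4))
        roi = np.zeros((4, 4), bool)
        roi[0, 0] = True
        with pytest.raises(ValueError, match="nonempty"):
            extract_roi_trace(stack, roi, np.zeros((4, 4), bool))


class TestFitBleach:
    def test_constant_trace_collapses_to_offset(self):
        t = np.arange(0, 30, 1 / 38.9)
        tr = RoiTrace("r", t, np.full_like(t, 42.0))
        fit = fit_bleach(tr)
        np.testing.assert_allclose(fit.f0, 42.0)
        dff = compute_dff(tr, fit)
        np.testing.assert_allclose(dff.dff, 0.0)

    def test_noiseless_two_exponential_recovery_to_1e3(self):
        t = np.arange(0, 170, 1 / 38.9)
        F = 1000 * (0.7 * np.exp(-t / 20) + 0.3 * np.exp(-t / 200) + 0.25)
        fit = fit_bleach(RoiTrace("r", t, F))
        assert fit.tau1_s == pytest.approx(20.0, rel=1e-3)
        assert fit.tau2_s == pytest.approx(200.0, rel=1e-3)
        assert fit.a1 == pytest.approx(700.0, rel=1e-3)
        assert fit.a2 == pytest.approx(300.0, rel=1e-3)
        assert fit.offset == pytest.approx(250.0, rel=1e-3)

    def test_gray_window_mask_covers_last_quarter(self, flash_spec):
        log = build_stimulus_log(flash_spec, 4)
        t = np.arange(0, log.duration_s, 1 / 38.9)
        tr = RoiTrace("r", t, np.ones_like(t))
        mask = fitting_mask(tr, "last_25pct_gray", log)
        # every masked frame sits in the final 375 ms of some gray period
        from flpstop_pipeline.stimulus import gray_periods
        periods = gray_periods(log)
        for ti in t[mask]:
            assert any(end - 0.25 * (end - start) <= ti < end for start, end in periods)
        # and frames in those windows are all selected
        expected = np.zeros_like(mask)
        for start, end in periods:
            expected |= (t >= end - 0.25 * (end - start)) & (t < end)
        np.testing.assert_array_equal(mask, expected)

    def test_mask_too_small_rejected(self):
        t = np.arange(5) / 38.9
        tr = RoiTrace("r", t, np.exp(-t))
        with pytest.raises(ValueError, match="at least"):
            fit_bleach(tr)

    def test_zero_mean_residual_over_fitting_mask(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 60, 1 / 38.9)
        F = 800 * (0.5 * np.exp(-t / 15) + 0.5) + rng.normal(0, 5, t.size)
        tr = RoiTrace("r", t, F)
        fit = fit_bleach(tr)
        dff = compute_dff(tr, fit)
        assert abs(dff.dff[fit.mask].mean()) < 1e-3


class TestComputeDff:
    def test_f_equals_f0_gives_zero(self):
        t = np.arange(10) / 38.9
        f0 = np.full(10, 5.0)
        fit = BleachFit(0, 1, 0, 1, 5.0, "all_frames", np.ones(10, bool), f0)
        tr = RoiTrace("r", t, f0.copy())
        np.testing.assert_array_equal(compute_dff(tr, fit).dff, 0.0)

    def test_f_twice_f0_gives_one(self):
        t = np.arange(10) / 38.9
        f0 = np.full(10, 5.0)
        fit = BleachFit(0, 1, 0, 1, 5.0, "all_frames", np.ones(10, bool), f0)
        tr = RoiTrace("r", t, 2 * f0)
        np.testing.assert_allclose(compute_dff(tr, fit).dff, 1.0)

    def test_nonpositive_f0_rejected(self):
        t = np.arange(10) / 38.9
        f0 = np.zeros(10)
        fit = BleachFit(0, 1, 0, 1, 0.0, "all_frames", np.ones(10, bool), f0)
        with pytest.raises(ValueError):
            compute_dff(RoiTrace("r", t, f0), fit)

    def test_noiseless_synthetic_peak_matches_programmed_amplitude(self, noiseless_cfg):
        cfg = dataclasses.replace(noiseless_cfg, n_trials=3)
        traces, log, truth = generate_roi_traces(cfg)
        tr = traces[0]
        clog = compensate_delay(log)
        fit = fit_bleach(tr, "last_25pct_gray", log=clog)
        dff = compute_dff(tr, fit)
        # frames sample the kernel up to half a frame period off its peak,
        # so the observed maximum sits a few percent below the programmed
        # amplitude but never above it
        assert cfg.amp * 0.95 <= dff.dff.max() <= cfg.amp * 1.001


class TestStimulusLockedAverage:
    def test_grid_spacing_is_exactly_shift(self, noiseless_cfg):
        traces, log, _ = generate_roi_traces(noiseless_cfg)
        clog = compensate_delay(log)
        fit = fit_bleach(traces[0], "last_25pct_gray", log=clog)
        avg = stimulus_locked_average(compute_dff(traces[0], fit), clog, "to_light")
        np.testing.assert_allclose(np.diff(avg.grid_s), avg.shift_s, atol=1e-12)
        assert avg.effective_rate_hz == pytest.approx(120.0, abs=0.5)

    def test_three_bin_sample_sharing(self):
        """window/shift = 25/8.33 → each interior sample lands in 3 bins."""
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0.5, 2.5, 40))
        dff = DffTrace(times, rng.normal(size=40))
        log = StimulusLog(
            spec=StimulusSpec.flash_off_gray(),
            transitions=(Transition(1.5, "to_light"), Transition(1.525, "to_gray")),
        )
        avg = stimulus_locked_average(dff, log, "to_light",
                                      pre_s=1.0, post_s=1.0)
        rel = times - 1.5
        interior = (rel > -1.0 + avg.window_s) & (rel < 1.0 - avg.window_s)
        counts = np.zeros(len(times), int)
        for i, r in enumerate(rel):
            counts[i] = np.sum(np.abs(avg.grid_s - r) <= avg.window_s / 2)
        assert np.all(counts[interior] == 3)
        assert avg.n_per_bin.sum() == counts.sum()

    def test_identity_mapping_with_narrow_window(self):
        # samples exactly on the grid, window below the frame period
        times = 1.5 + np.arange(5) * 0.01
        vals = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        log = StimulusLog(
            spec=StimulusSpec.flash_off_gray(),
            transitions=(Transition(1.5, "to_light"),),
        )
        avg = stimulus_locked_average(DffTrace(times, vals), log, "to_light",
                                      window_s=0.01, shift_s=0.01,
                                      pre_s=0.0, post_s=0.04)
        np.testing.assert_allclose(avg.mean_dff, vals, atol=1e-12)
        np.testing.assert_array_equal(avg.n_per_bin, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(50, 200)
        times = np.sort(rng.uniform(0, 20, n))
        times = np.unique(times)
        vals = rng.normal(size=times.size)
        trans_t = np.sort(rng.uniform(2, 18, rng.integers(1, 6)))
        trans = tuple(Transition(float(t), "to_light") for t in np.unique(trans_t))
        log = StimulusLog(spec=StimulusSpec.flash_off_gray(), transitions=trans)
        w = float(rng.uniform(0.02, 0.2))
        s = w / float(rng.integers(1, 4))
        avg = stimulus_locked_average(DffTrace(times, vals), log, "to_light",
                                      window_s=w, shift_s=s, pre_s=0.5, post_s=1.0)
        g, m, nn = brute_force_stim_locked(
            DffTrace(times, vals), log, "to_light", w, s, 0.5, 1.0)
        np.testing.assert_allclose(avg.grid_s, g, atol=1e-12)
        np.testing.assert_array_equal(avg.n_per_bin, nn)
        np.testing.assert_allclose(avg.mean_dff, m, rtol=1e-12, atol=1e-14)

    def test_window_change_keeps_grid(self):
        times = np.arange(0, 10, 1 / 38.9)
        vals = np.sin(times)
        log = StimulusLog(spec=StimulusSpec.flash_off_gray(),
                          transitions=(Transition(5.0, "to_light"),))
        a1 = stimulus_locked_average(DffTrace(times, vals), log, "to_light",
                                     window_s=0.025)
        a2 = stimulus_locked_average(DffTrace(times, vals), log, "to_light",
                                     window_s=0.1)
        # both grids sit on the same lattice -pre + k*shift; a wider window
        # only changes smoothing (and which edge bins are nonempty)
        for avg in (a1, a2):
            k = (avg.grid_s + 0.5) / avg.shift_s
            np.testing.assert_allclose(k, np.round(k), atol=1e-9)
        assert a1.shift_s == a2.shift_s


class TestResponderAndPeak:
    @staticmethod
    def _avg_from(mean, grid=None):
        from flpstop_pipeline.traces import StimLockedAverage
        mean = np.asarray(mean, float)
        if grid is None:
            grid = np.arange(len(mean)) * 0.00833 - 0.5
        return StimLockedAverage(
            grid_s=grid, mean_dff=mean, sem_dff=np.zeros_like(mean),
            n_per_bin=np.ones(len(mean), int), window_s=0.025, shift_s=0.00833,
            transition_type="to_light",
        )

    def test_programmed_five_sigma_responder_detected(self):
        rng = np.random.default_rng(0)
        n = 180
        grid = np.arange(n) * 0.00833 - 0.5
        sigma = 0.02
        mean = rng.normal(0, sigma, n)
        mean[(grid > 0.05) & (grid < 0.15)] += 5 * sigma
        assert identify_responder(self._avg_from(mean, grid), k_sigma=3.0)

    def test_flat_noise_false_positive_rate_matches_gaussian_oracle(self):
        """On pure Gaussian bins the k=3 responder rule fires at the rate a
        direct Monte-Carlo of the same max-vs-estimated-sigma statistic
        predicts."""
        n = 180
        grid = np.arange(n) * 0.00833 - 0.5
        base = (grid >= -0.5) & (grid < 0.0)
        resp = (grid >= 0.0) & (grid < 1.0)

        rng = np.random.default_rng(1)
        hits = sum(
            identify_responder(self._avg_from(rng.normal(0, 0.02, n), grid))
            for _ in range(400)
        )
        # independent oracle for the same statistic
        rng2 = np.random.default_rng(2)
        oracle_hits = 0
        n_oracle = 4000
        for _ in range(n_oracle):
            x = rng2.normal(0, 0.02, n)
            if np.max(np.abs(x[resp])) > 3 * np.std(x[base], ddof=1):
                oracle_hits += 1
        p = oracle_hits / n_oracle
        se = np.sqrt(p * (1 - p) * (1 / 400 + 1 / n_oracle)) * 400
        assert abs(hits - 400 * p) <= 4 * max(se, 1.0)

    def test_all_zero_trace_is_not_responder(self):
        assert not identify_responder(self._avg_from(np.zeros(180)))

    def test_peak_takes_directional_extreme(self):
        grid = np.linspace(0, 0.5, 61)
        mean = np.zeros(61)
        mean[10] = 0.8
        mean[30] = -0.3
        avg = self._avg_from(mean, grid)
        pk = peak_response(avg, "increase", (0.0, 0.5))
        assert pk.value == pytest.approx(0.8)
        assert pk.time_s == pytest.approx(grid[10])
        pk = peak_response(avg, "decrease", (0.0, 0.5))
        assert pk.value == pytest.approx(-0.3)

    def test_all_zero_trace_peak_zero(self):
        avg = self._avg_from(np.zeros(61), np.linspace(0, 0.5, 61))
        assert peak_response(avg, "increase", (0.0, 0.5)).value == 0.0


class TestNormalizePeaks:
    def test_simple_normalization(self):
        df = pd.DataFrame({
            "genotype": ["no_flp_control", "no_flp_control", "experimental"],
            "peak": [1.0, 1.0, 2.0],
        })
        out = normalize_peaks(df)
        assert out.loc[2, "normalized_peak"] == pytest.approx(2.0)

    def test_control_mean_is_exactly_one(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "genotype": ["no_flp_control"] * 10 + ["experimental"] * 5,
            "peak": rng.uniform(0.2, 1.5, 15),
        })
        out = normalize_peaks(df)
        ctrl = out[out["genotype"] == "no_flp_control"]["normalized_peak"]
        assert ctrl.mean() == pytest.approx(1.0, abs=1e-12)

    def test_empty_control_rejected(self):
        df = pd.DataFrame({"genotype": ["experimental"], "peak": [1.0]})
        with pytest.raises(ValueError, match="control"):
            normalize_peaks(df)


class TestMonotonicity:
    def test_recovered_peak_increases_with_programmed_amplitude(self):
        peaks = []
        for amp in (0.2, 0.4, 0.8):
            cfg = SimConfig(seed=5, noise_sd=0.0, bleach_jitter_cv=0.0,
                            n_rois=1, n_trials=4, amp=amp,
                            conditions=[("no_flp_control", "M5")])
            traces, log, _ = generate_roi_traces(cfg)
            clog = compensate_delay(log)
            fit = fit_bleach(traces[0], "last_25pct_gray", log=clog)
            avg = stimulus_locked_average(compute_dff(traces[0], fit), clog, "to_light")
            peaks.append(peak_response(avg, "increase", (0.0, 0.5)).value)
        assert peaks[0] < peaks[1] < peaks[2]
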