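"""Temporal preprocessing, frame metrics and censoring."""

import numpy as np
import pytest
from scipy import signal as sps

import dmndyn as dd
from dmndyn import preprocess as pp
from dmndyn._filters import sosfiltfilt
from dmndyn.containers import BoldRun, MotionTrace


def _make_run(data, tr=2.0, brain=None):
    data = np.asarray(data, dtype=np.float32)
    brain = np.ones(data.shape[:3], bool) if brain is None else brain
    return BoldRun(
        subject="sub-00", state="R1", data=data, tr=tr,
        affine=np.diag([3.0, 3.0, 3.0, 1.0]), brain_mask=brain,
    )


class TestDropInitial:
    def test_150_frames_become_140(self, tiny_subject):
        run = tiny_subject.runs["R1"]
        out = pp.drop_initial(_make_run(np.zeros((2, 2, 2, 150))))
        assert out.n_frames == 140
        assert out.history == ["drop_initial"]

    def test_zero_drop_is_identity(self):
        run = _make_run(np.random.rand(2, 2, 2, 20))
        out = pp.drop_initial(run, 0)
        assert np.array_equal(out.data, run.data)

    def test_short_run_raises(self):
        with pytest.raises(ValueError, match="cannot drop"):
            pp.drop_initial(_make_run(np.zeros((2, 2, 2, 5))), 10)


class TestSmoothing:
    def test_impulse_matches_analytic_gaussian(self):
        """A central impulse smooths to the closed-form Gaussian profile."""
        n = 25
        data = np.zeros((n, n, n, 1), np.float32)
        data[12, 12, 12, 0] = 1.0
        out = pp.smooth_spatial(_make_run(data), fwhm_mm=8.0)
        sigma = pp.fwhm_to_sigma(8.0, 3.0)
        x = np.arange(n) - 12.0
        g = np.exp(-x**2 / (2 * sigma**2))
        g /= g.sum()
        expected = g[:, None, None] * g[None, :, None] * g[None, None, :]
        assert np.abs(out.data[..., 0] - expected).max() < 1e-4

    def test_total_sum_preserved_under_reflection(self):
        data = np.random.default_rng(0).random((12, 14, 12, 3)).astype(np.float32)
        out = pp.smooth_spatial(_make_run(data), fwhm_mm=8.0)
        for t in range(3):
            a, b = data[..., t].sum(dtype=np.float64), out.data[..., t].sum(dtype=np.float64)
            assert abs(a - b) / abs(a) < 1e-6

    def test_constant_volume_unchanged_and_zero_fwhm_identity(self):
        data = np.full((8, 8, 8, 2), 7.0, np.float32)
        out = pp.smooth_spatial(_make_run(data), fwhm_mm=8.0)
        assert np.allclose(out.data, 7.0, atol=1e-4)
        out0 = pp.smooth_spatial(_make_run(data), fwhm_mm=0.0)
        assert np.array_equal(out0.data, data)

    def test_negative_fwhm_raises(self):
        with pytest.raises(ValueError):
            pp.smooth_spatial(_make_run(np.zeros((4, 4, 4, 1))), -1.0)


class TestBandpass:
    def _gain(self, freq, n=140, tr=2.0):
        t = np.arange(n) * tr
        x = np.sin(2 * np.pi * freq * t)
        y = pp.bandpass_series(x, tr)
        # compare amplitudes at the probe frequency via FFT
        f = np.fft.rfftfreq(n, tr)
        k = np.argmin(np.abs(f - freq))
        return np.abs(np.fft.rfft(y))[k] / np.abs(np.fft.rfft(x))[k]

    def test_in_band_amplitude_preserved(self):
        assert 0.95 <= self._gain(0.04) <= 1.05

    def test_stop_band_attenuated(self):
        assert self._gain(0.2) <= 0.1

    def test_dc_removed(self):
        y = pp.bandpass_series(np.full(140, 5.0), 2.0)
        assert np.abs(y).max() < 1e-6

    def test_band_outside_nyquist_raises(self):
        with pytest.raises(ValueError, match="Nyquist"):
            pp.bandpass_series(np.zeros(140), 2.0, 0.008, 0.3)

    def test_too_short_run_raises(self):
        with pytest.raises(ValueError, match="too short"):
            pp.bandpass_series(np.zeros(20), 2.0)

    def test_fast_filter_equals_scipy_oracle(self):
        sos = sps.butter(4, [0.008, 0.08], btype="bandpass", fs=0.5,
                         output="sos")
        x = np.random.default_rng(3).normal(size=(40, 140))
        assert np.allclose(sosfiltfilt(sos, x),
                           sps.sosfiltfilt(sos, x, axis=-1), atol=1e-10)


class TestNuisanceRegression:
    def test_residuals_orthogonal_to_design(self, rng):
        series = rng.normal(size=(30, 100))
        design = np.column_stack([np.ones(100), rng.normal(size=(100, 8))])
        res = pp.regress_series(series, design)
        dots = res @ design
        norms = np.linalg.norm(res, axis=1)[:, None] * np.linalg.norm(design, axis=0)
        assert np.abs(dots / np.maximum(norms, 1e-30)).max() < 1e-8

    def test_recovers_signal_mixed_with_orthogonal_regressor(self, rng):
        t = np.arange(128)
        wm = np.cos(2 * np.pi * 8 * t / 128)
        signal = np.sin(2 * np.pi * 8 * t / 128)  # orthogonal to wm
        series = (signal + 0.7 * wm)[None, :]
        design = np.column_stack([np.ones(128), wm])
        res = pp.regress_series(series, design)
        assert np.abs(res[0] - signal).max() < 1e-8

    def test_intercept_only_demeans(self):
        series = np.full((1, 50), 5.0)
        res = pp.regress_series(series, np.ones((50, 1)))
        assert np.abs(res).max() < 1e-10

    def test_rank_deficient_design_warns(self, rng):
        x = rng.normal(size=100)
        design = np.column_stack([np.ones(100), x, 2 * x])
        with pytest.warns(UserWarning, match="rank-deficient"):
            pp.regress_series(rng.normal(size=(3, 100)), design)

    def test_length_mismatch_raises(self, rng):
        with pytest.raises(ValueError, match="rows"):
            pp.regress_series(rng.normal(size=(3, 100)),
                              np.ones((99, 2)))

    def test_voxel_equal_to_global_regressor_zeroed(self, tiny_subject):
        run = tiny_subject.runs["R1"]
        run = pp.drop_initial(run)
        out = pp.regress_nuisance(run, motion=None, global_signal=True)
        gs_before = run.data[run.brain_mask].mean(axis=0)
        # the global signal itself is annihilated by the regression
        proj = out.data[run.brain_mask].mean(axis=0)
        assert np.abs(proj).max() < 1e-2 * np.std(gs_before)


class TestFrameMetrics:
    def test_motionless_constant_run_all_zero(self):
        run = _make_run(np.full((4, 4, 4, 20), 100.0))
        mot = MotionTrace(params=np.zeros((20, 6)))
        m = pp.compute_frame_metrics(run, mot)
        assert np.all(m.fd == 0) and np.all(m.gs_pct == 0)

    def test_fd_single_translation_step(self):
        params = np.zeros((20, 6))
        params[10:, 0] = 0.5  # x jumps by 0.5 mm between frames 9 and 10
        fd = pp.framewise_displacement(params)
        assert fd[10] == pytest.approx(0.5)
        assert np.all(np.delete(fd, 10) == 0)

    def test_fd_rotation_radius(self):
        params = np.zeros((5, 6))
        params[2:, 4] = 0.01  # 0.01 rad pitch step
        fd = pp.framewise_displacement(params)
        assert fd[2] == pytest.approx(0.5)  # 50 mm * 0.01

    def test_gs_step_percent_change(self):
        data = np.full((4, 4, 4, 10), 100.0, np.float32)
        data[..., 5:] = 101.0
        run = _make_run(data)
        m = pp.compute_frame_metrics(run, MotionTrace(params=np.zeros((10, 6))))
        mean_gs = data.mean()
        assert m.gs_pct[5] == pytest.approx(1.0 / mean_gs * 100, rel=1e-4)

    def test_zero_mean_global_signal_raises(self):
        run = _make_run(np.zeros((4, 4, 4, 10)))
        with pytest.raises(ValueError, match="zero mean"):
            pp.compute_frame_metrics(run, MotionTrace(params=np.zeros((10, 6))))


class TestScrub:
    def _run_with_metrics(self, n, flags):
        run = _make_run(np.random.rand(3, 3, 3, n).astype(np.float32) + 100)
        fd = np.zeros(n)
        gs = np.zeros(n)
        fd[flags] = 0.6
        gs[flags] = 0.8
        metrics = MotionTrace(params=np.zeros((n, 6)), fd=fd, gs_pct=gs)
        return run, metrics

    def test_single_flag_removes_four_frame_window(self):
        run, metrics = self._run_with_metrics(140, [50])
        out, report = pp.scrub(run, metrics)
        assert list(report.removed) == [49, 50, 51, 52]
        assert out.n_frames == 136

    def test_and_rule_keeps_partial_threshold_frames(self):
        run = _make_run(np.random.rand(3, 3, 3, 60).astype(np.float32) + 100)
        fd = np.zeros(60)
        gs = np.zeros(60)
        fd[20] = 0.6   # displacement over threshold but GS quiet
        gs[40] = 0.8   # GS over threshold but no motion
        metrics = MotionTrace(params=np.zeros((60, 6)), fd=fd, gs_pct=gs)
        _, report = pp.scrub(run, metrics)
        assert report.n_removed == 0

    def test_17_spaced_flags_trigger_exclusion(self):
        flags = list(range(5, 5 + 17 * 8, 8))  # 17 flags, >= 5 frames apart
        run, metrics = self._run_with_metrics(150, flags)
        _, report = pp.scrub(run, metrics)
        assert report.n_removed == 68
        assert report.excluded  # 68 > 60

    def test_windows_clipped_at_edges(self):
        run, metrics = self._run_with_metrics(20, [0, 19])
        _, report = pp.scrub(run, metrics)
        assert set(report.removed) == {0, 1, 2, 18, 19}

    def test_overlapping_windows_merge(self):
        run, metrics = self._run_with_metrics(50, [10, 12])
        _, report = pp.scrub(run, metrics)
        assert list(report.removed) == [9, 10, 11, 12, 13, 14]

    def test_scrubbing_idempotent(self):
        run, metrics = self._run_with_metrics(100, [30])
        out, report = pp.scrub(run, metrics)
        clean_fd = np.delete(metrics.fd, report.removed)
        clean_gs = np.delete(metrics.gs_pct, report.removed)
        metrics2 = MotionTrace(params=np.zeros((out.n_frames, 6)),
                               fd=clean_fd, gs_pct=clean_gs)
        out2 = BoldRun(subject="s", state="R1", data=out.data, tr=2.0,
                       affine=out.affine, brain_mask=out.brain_mask)
        _, report2 = pp.scrub(out2, metrics2)
        assert report2.n_removed == 0


class TestPipelineOrder:
    def test_rerunning_a_step_raises(self):
        run = pp.drop_initial(_make_run(np.zeros((3, 3, 3, 40))), 5)
        with pytest.raises(ValueError, match="already applied"):
            pp.drop_initial(run, 5)

    def test_out_of_order_step_raises(self):
        run = _make_run(np.random.rand(3, 3, 3, 60).astype(np.float32))
        run = pp.bandpass(run)
        with pytest.raises(ValueError, match="pipeline order"):
            pp.smooth_spatial(run, 8.0)

    def test_history_records_full_chain(self, tiny_subject):
        run, report = pp.preprocess_run(
            tiny_subject.runs["T1"], tiny_subject.motion["T1"]
        )
        assert run.history == ["drop_initial", "smooth_spatial", "bandpass",
                               "regress_nuisance", "scrub"]


def test_lean_pipeline_path_matches_reference(tiny_subject):
    """The array-level fast path equals the BoldRun-level chain."""
    from dmndyn.pipeline import PipelineConfig, preprocess_series

    run, mot = tiny_subject.runs["T2"], tiny_subject.motion["T2"]
    ref_run, ref_rep = pp.preprocess_run(run, mot)
    lean, rep = preprocess_series(run, mot, PipelineConfig())
    ref = ref_run.data[run.brain_mask].astype(np.float64)
    scale = np.abs(ref).max()
    assert np.abs(ref - lean.astype(np.float64)).max() < 1e-3 * scale
    assert np.array_equal(ref_rep.removed, rep.removed)
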