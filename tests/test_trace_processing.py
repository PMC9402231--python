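"""Filtering, neuropil correction, ΔF/F and active-period detection."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from calsync import (FilterSettings, SimulationConfig, TraceProcessor,
                     bandpass_filter, butterworth_highcut, compute_dff,
                     correct_neuropil, detect_active_periods,
                     estimate_contamination_ratio, find_baseline_mask,
                     process_recording, simulate_recording)

FR = 4.0


def _sine(freq_hz, duration_s=600.0, frame_rate=FR, amplitude=1.0):
    t = np.arange(int(duration_s * frame_rate)) / frame_rate
    return amplitude * np.sin(2 * np.pi * freq_hz * t), t


class TestBandpassFilter:
    def test_constant_trace_maps_to_zero(self):
        out = bandpass_filter(np.full(2400, 57.0), FR)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_nyquist_sinusoid_rejected(self):
        """A 2 Hz oscillation sampled at 4 Hz is outside the passband."""
        t = np.arange(2400) / FR
        x = np.cos(2 * np.pi * 2.0 * t)
        y = bandpass_filter(x, FR)
        assert np.abs(y[200:-200]).max() < 0.05 * np.abs(x).max()

    def test_slow_sinusoid_passes(self):
        """0.1 Hz sits between the low-cut (1/120 Hz) and high-cut (1 Hz)."""
        x, _ = _sine(0.1)
        y = bandpass_filter(x, FR)
        assert np.abs(y[400:-400]).max() == pytest.approx(1.0, rel=0.10)

    def test_zero_phase_preserves_symmetry(self):
        """A symmetric pulse stays symmetric: no onset-time shift."""
        n = 801
        t = (np.arange(n) - n // 2) / FR
        x = np.exp(-0.5 * (t / 2.0) ** 2)
        y = bandpass_filter(x, FR)
        np.testing.assert_allclose(y, y[::-1], atol=1e-6 * np.abs(y).max())

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            butterworth_highcut(np.zeros(500), 2.0,
                                FilterSettings(highcut_period_s=1.0))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            butterworth_highcut(np.zeros(50), FR)


class TestBaselineMask:
    def test_silent_recording_masks_every_frame(self, quiet_sim_config):
        rec, _ = simulate_recording(quiet_sim_config)
        mask = find_baseline_mask(rec.cell_traces[0], rec.surround_traces[0],
                                  FR)
        assert mask.all()

    def test_mask_excludes_event_frames(self):
        cfg = SimulationConfig(n_cells=40, duration_s=240.0, seed=11)
        rec, truth = simulate_recording(cfg)
        mask = find_baseline_mask(rec.cell_traces, rec.surround_traces, FR)
        event_frames = np.zeros(cfg.n_frames, dtype=bool)
        for e in truth.events:
            event_frames[e.onset_frame:e.offset_frame] = True
        excluded = 1.0 - mask[:, event_frames].mean()
        assert excluded >= 0.90

    def test_nan_input_rejected(self):
        bad = np.full(500, np.nan)
        with pytest.raises(ValueError, match="NaN"):
            find_baseline_mask(bad, bad, FR)

    def test_tiny_mask_advises_larger_quantile(self, rng):
        x = rng.normal(size=(500,))
        with pytest.raises(ValueError, match="quantile"):
            find_baseline_mask(x, x, FR, quantile=0.5, min_frames=400)


class TestContaminationRatio:
    def test_exact_linear_relation_recovers_r(self, rng):
        surround = rng.normal(10.0, 2.0, size=2000)
        cell = 0.7 * (surround - surround.mean()) + 42.0
        est = estimate_contamination_ratio(cell, surround,
                                           np.ones(2000, dtype=bool))
        assert est.r == pytest.approx(0.7, abs=1e-12)
        assert est.fit_residual == pytest.approx(0.0, abs=1e-18)

    def test_independent_noise_gives_near_zero_r(self):
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            cell = rng.normal(size=5000)
            surround = rng.normal(size=5000)
            est = estimate_contamination_ratio(cell, surround,
                                               np.ones(5000, dtype=bool))
            estimates.append(est.r)
        assert np.max(np.abs(estimates)) < 0.05
        assert abs(np.mean(estimates)) < 0.01

    def test_constant_surround_rejected(self):
        cell = np.random.default_rng(0).normal(size=200)
        with pytest.raises(ValueError, match="unidentifiable|constant"):
            estimate_contamination_ratio(cell, np.full(200, 3.0),
                                         np.ones(200, dtype=bool))

    def test_matches_grid_search_minimiser(self, rng):
        """Closed form agrees with 1-D brute-force SSR minimisation."""
        grid = np.arange(-0.5, 1.5, 1e-4)
        for _ in range(20):
            n = int(rng.integers(30, 120))
            surround = rng.normal(size=n)
            cell = (rng.uniform(0, 1) * surround + 0.3 * rng.normal(size=n))
            est = estimate_contamination_ratio(cell, surround,
                                               np.ones(n, dtype=bool))
            x = surround - surround.mean()
            y = cell - cell.mean()
            ssr = (y @ y) - 2 * grid * (x @ y) + grid ** 2 * (x @ x)
            assert abs(est.r - grid[np.argmin(ssr)]) <= 1e-3


class TestCorrectNeuropil:
    def test_r_zero_is_identity(self, rng):
        cell = rng.normal(size=300)
        out = correct_neuropil(cell, rng.normal(size=300), 0.0)
        np.testing.assert_array_equal(out, cell)

    def test_mean_is_preserved(self, rng):
        cell = rng.normal(5.0, 1.0, size=400)
        surround = rng.normal(3.0, 1.0, size=400)
        out = correct_neuropil(cell, surround, 0.8)
        assert out.mean() == pytest.approx(cell.mean(), abs=1e-12)

    @given(r1=st.floats(-1, 1), r2=st.floats(-1, 1),
           a=st.floats(-2, 2))
    def test_linear_in_r_and_inputs(self, r1, r2, a):
        rng = np.random.default_rng(99)
        cell = rng.normal(size=100)
        surround = rng.normal(size=100)
        lhs = correct_neuropil(cell, surround, r1 + r2)
        rhs = (correct_neuropil(cell, surround, r1)
               + correct_neuropil(np.zeros(100), surround, r2))
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)
        np.testing.assert_allclose(correct_neuropil(a * cell, surround, r1),
                                   a * cell - r1 * (surround - surround.mean()),
                                   atol=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="share shape"):
            correct_neuropil(np.zeros(10), np.zeros(11), 0.5)


class TestComputeDff:
    def test_constant_trace_gives_zeros(self):
        dff = compute_dff(np.full(1000, 100.0), frame_rate_hz=FR)
        np.testing.assert_allclose(dff.values, 0.0, atol=1e-12)

    def test_five_percent_excursion_is_definitional(self):
        trace = np.full(1000, 100.0)
        trace[500] = 105.0
        dff = compute_dff(trace, f0_method="global_percentile",
                          frame_rate_hz=FR)
        assert dff.values[500] == pytest.approx(0.05, abs=1e-12)

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(ValueError, match="F0"):
            compute_dff(np.full(500, -5.0), f0_method="global_percentile")

    def test_transient_amplitude_survives_preprocessing(self):
        """A generated 0.15 ΔF/F transient comes out within 20% of 0.15."""
        cfg = SimulationConfig(n_cells=20, duration_s=240.0, noise_sd=0.0,
                               seed=21)
        rec, truth = simulate_recording(cfg)
        processed = process_recording(rec)
        event = max(truth.events, key=lambda e: e.offset_frame - e.onset_frame)
        cell = event.participants[0]
        peak = processed.dff[cell, event.onset_frame:event.offset_frame].max()
        assert peak == pytest.approx(cfg.transient_amplitude, rel=0.20)


class TestDetectActivePeriods:
    def test_threshold_is_exclusive_below(self):
        assert not detect_active_periods(np.full(100, 0.04)).any()

    def test_threshold_is_inclusive_above(self):
        assert detect_active_periods(np.full(100, 0.10)).all()

    def test_empty_trace_gives_empty_mask(self):
        assert detect_active_periods(np.array([])).size == 0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            detect_active_periods(np.zeros(10), threshold=0.0)


class TestFullPreprocessing:
    def test_noise_free_raster_matches_ground_truth(self):
        """Noise-free round trip: active frames cover the true event frames
        and are absent far from any event."""
        cfg = SimulationConfig(n_cells=40, duration_s=300.0, noise_sd=0.0,
                               seed=13)
        rec, truth = simulate_recording(cfg)
        processed = process_recording(rec)
        raster = processed.raster

        margin = 8   # frames; calcium decay tail allowance
        near_event = np.zeros(cfg.n_frames, dtype=bool)
        covered, total = 0, 0
        for e in truth.events:
            lo = max(e.onset_frame - margin, 0)
            near_event[lo:e.offset_frame + margin] = True
            sub = raster[e.participants, e.onset_frame:e.offset_frame]
            covered += int(sub.sum())
            total += sub.size
        assert covered / total >= 0.95
        silent_active = raster[:, ~near_event].mean()
        assert silent_active <= 0.01

    def test_estimator_recovers_contamination_ratio(self):
        """Per-cell r from quiet frames lands close to the generative value.

        Conditioning the baseline mask on the cell's own activity score
        induces a small negative selection bias, so recovery is close but
        not exact even without noise.
        """
        cfg = SimulationConfig(n_cells=30, duration_s=240.0, noise_sd=0.0,
                               contamination_r=0.6, seed=17)
        rec, _ = simulate_recording(cfg)
        proc = TraceProcessor().fit(rec.cell_traces,
                                    surround=rec.surround_traces,
                                    frame_rate_hz=FR)
        np.testing.assert_allclose(proc.r_, 0.6, atol=0.05)
        assert abs(proc.r_.mean() - 0.6) < 0.03

    def test_sklearn_param_interface(self):
        proc = TraceProcessor(dff_threshold=0.07)
        assert proc.get_params()["dff_threshold"] == 0.07
        proc.set_params(f0_percentile=20.0)
        assert proc.f0_percentile == 20.0
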