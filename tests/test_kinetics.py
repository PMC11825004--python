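"""Frequency extraction, zero-phase filtering, cycle segmentation and
per-cycle timing metrics against closed forms."""

import numpy as np
import pytest

import pillartrack as pt
from pillartrack.errors import NoCompleteCycleError, PillarTrackError
from pillartrack.kinetics import _cross_time  # noqa: F401  (used indirectly)


class TestDominantFrequency:
    def test_paced_2hz_sinusoid(self):
        t = np.arange(1000) / 100.0
        assert pt.dominant_frequency(np.sin(2 * np.pi * 2.0 * t), 100) == \
            pytest.approx(2.0, abs=0.1)

    def test_spontaneous_like_1p2hz(self):
        x = pt.waveform_trace("spont", 1.2, 100, 10, amplitude=4,
                              noise_sigma=0.2, seed=2)
        assert pt.dominant_frequency(x, 100) == pytest.approx(1.2, abs=0.1)

    def test_white_noise_takes_warning_path(self):
        # realization verified to have no in-band peak 3x above the
        # spectral median (the no-periodicity criterion)
        x = np.random.default_rng(1).normal(0, 1, 1000)
        with pytest.warns(UserWarning, match="no periodic"):
            assert pt.dominant_frequency(x, 100) is None

    def test_too_short_trace_rejected(self):
        with pytest.raises(PillarTrackError, match="2 s"):
            pt.dominant_frequency(np.zeros(100), 100)


class TestLowpass:
    def test_dc_signal_unchanged(self):
        x = np.full(500, 3.7)
        assert np.allclose(pt.lowpass(x, 2.0, 100), x, atol=1e-9)

    def test_band_separation_2hz_kept_40hz_killed(self):
        t = np.arange(1000) / 100.0
        x = np.sin(2 * np.pi * 2 * t) + np.sin(2 * np.pi * 40 * t)
        y = pt.lowpass(x, 2.0, 100)

        def band_amp(sig, f):
            spec = np.abs(np.fft.rfft(sig)) / len(sig) * 2
            return spec[int(round(f * len(sig) / 100))]

        assert band_amp(y, 40) < band_amp(x, 40) / 10
        assert band_amp(y, 2) == pytest.approx(band_amp(x, 2), rel=0.05)

    def test_near_idempotent_below_cutoff(self):
        x = pt.waveform_trace("pulse", 2.0, 100, 10, amplitude=3,
                              noise_sigma=0.1, seed=3)
        once = pt.lowpass(x, 2.0, 100)
        twice = pt.lowpass(once, 2.0, 100)
        rms = np.sqrt(np.mean((twice - once) ** 2))
        assert rms < 0.01 * np.sqrt(np.mean(once ** 2))

    def test_infeasible_cutoff_rejected(self):
        with pytest.raises(PillarTrackError):
            pt.lowpass(np.zeros(100), 0.0, -100)


class TestSegmentCycles:
    def test_ten_seconds_of_2hz_pulses_gives_19_cycles(self):
        x = pt.waveform_trace("pulse", 2.0, 100, 10, amplitude=5)
        cycles = pt.segment_cycles(pt.lowpass(x, 2.0, 100))
        assert len(cycles) in (18, 19, 20)
        for s, p, e in cycles:
            assert s < p < e

    def test_trace_starting_mid_upstroke_drops_first_peak(self):
        t = np.arange(500) / 100.0
        # starts rising from phase pi/4: no minimum before the first peak
        x = np.sin(2 * np.pi * 1.0 * t + np.pi / 4)
        cycles = pt.segment_cycles(x)
        first_peak = np.argmax(x[:100])
        assert all(p != first_peak for _, p, _ in cycles)

    def test_monotone_ramp_has_no_cycle(self):
        with pytest.raises(NoCompleteCycleError):
            pt.segment_cycles(np.linspace(0, 1, 200))

    def test_cycles_share_boundary_minima_only(self):
        x = pt.waveform_trace("sine", 2.0, 100, 3, amplitude=2)
        cycles = pt.segment_cycles(x)
        for (s0, p0, e0), (s1, p1, e1) in zip(cycles, cycles[1:]):
            assert e0 <= s1 or e0 == s1


class TestCycleMetrics:
    def test_triangle_closed_form(self):
        # linear 0->1 uN over 0.5 s then back: T10 at 0.05 s, T90 at
        # 0.45 s, decay mirror-symmetric, both velocities 2 uN/s
        up = np.linspace(0, 1, 51)
        x = np.concatenate([up, up[::-1][1:]])
        m = pt.cycle_metrics(x, (0, 50, 100), 100.0)
        assert m.t_up10 == pytest.approx(0.05, abs=1e-9)
        assert m.t_up90 == pytest.approx(0.45, abs=1e-9)
        assert m.t_down90 == pytest.approx(0.05, abs=1e-9)
        assert m.t_down10 == pytest.approx(0.45, abs=1e-9)
        assert m.contraction_velocity == pytest.approx(2.0)
        assert m.relaxation_velocity == pytest.approx(2.0)

    def test_half_sine_matches_arcsine_closed_form(self):
        # x(t) = A sin(pi t / T): level q*A crossed at t = T asin(q)/pi
        fps, T, A = 100.0, 0.8, 3.0
        n = int(T * fps)
        t = np.arange(n + 1) / fps
        x = A * np.sin(np.pi * t / T)
        m = pt.cycle_metrics(x, (0, n // 2, n), fps)
        dt = 1.0 / fps
        assert m.t_up10 == pytest.approx(T * np.arcsin(0.1) / np.pi, abs=dt)
        assert m.t_up90 == pytest.approx(T * np.arcsin(0.9) / np.pi, abs=dt)
        # decay measured from the peak: T/2 - upstroke crossing time
        assert m.t_down90 == pytest.approx(
            T / 2 - T * np.arcsin(0.9) / np.pi, abs=dt)
        assert m.t_down10 == pytest.approx(
            T / 2 - T * np.arcsin(0.1) / np.pi, abs=dt)

    def test_velocities_scale_exactly_with_trace(self):
        x = pt.waveform_trace("pulse", 2.0, 100, 2, amplitude=1)
        cycles = pt.segment_cycles(x)
        m1 = pt.cycle_metrics(x, cycles[0], 100)
        m3 = pt.cycle_metrics(3 * x, cycles[0], 100)
        assert m3.contraction_velocity == pytest.approx(
            3 * m1.contraction_velocity, rel=1e-12)
        assert m3.relaxation_velocity == pytest.approx(
            3 * m1.relaxation_velocity, rel=1e-12)

    def test_flat_cycle_skipped(self):
        assert pt.cycle_metrics(np.zeros(50), (0, 25, 49), 100) is None

    def test_time_ordering_invariant_on_random_waveforms(self):
        rng = np.random.default_rng(9)
        checked = 0
        for _ in range(60):
            kind = rng.choice(["sine", "pulse", "spont"])
            f = rng.uniform(0.5, 3.0)
            x = pt.waveform_trace(kind, f, 100, 4,
                                  amplitude=rng.uniform(0.5, 8),
                                  noise_sigma=rng.uniform(0, 0.05),
                                  seed=int(rng.integers(2 ** 31)))
            filt = pt.lowpass(x, f, 100)
            try:
                cycles = pt.segment_cycles(filt)
            except NoCompleteCycleError:
                continue
            for cyc in cycles:
                m = pt.cycle_metrics(filt, cyc, 100)
                if m is None:
                    continue
                checked += 1
                assert 0 <= m.t_up10 < m.t_up90
                assert 0 <= m.t_down90 < m.t_down10
                assert m.contraction_velocity > 0
                assert m.relaxation_velocity > 0
                assert m.cycle_start_idx < m.peak_idx < m.cycle_end_idx
        assert checked > 100  # the sweep must actually exercise cycles

    def test_aggregate_reports_mean_and_sem(self):
        x = pt.waveform_trace("pulse", 2.0, 100, 6, amplitude=2)
        filt, f0, metrics = pt.analyze_trace(x, 100)
        agg = pt.aggregate_metrics(metrics)
        vals = [m.amplitude for m in metrics]
        assert agg["n_cycles"] == len(metrics) >= 8
        assert agg["amplitude_mean"] == pytest.approx(np.mean(vals))
        assert agg["amplitude_sem"] == pytest.approx(
            np.std(vals, ddof=1) / np.sqrt(len(vals)))
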