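"""Unit and property tests of the trace-preprocessing stages."""

import numpy as np
import pytest

from binomatch import (Baseline, compute_baseline,
                       cycle_average, detect_spikes, remove_spikes,
                       response_magnitude, smooth_current)
from binomatch.preprocess import CycleAveragedTrace

import oracles

FS = 10000.0


class TestDetectSpikes:
    def test_constant_trace_has_no_spikes(self):
        assert detect_spikes(np.full(5000, -60.0), FS).size == 0

    def test_injected_spikes_are_found_near_injection_times(self):
        rng = np.random.default_rng(0)
        trace = -60.0 + 0.05 * rng.normal(size=20000)
        true_times = [0.31, 0.87, 1.54]
        spike = np.concatenate([np.linspace(0, 80, 5, endpoint=False),
                                np.linspace(80, 0, 10)])
        for t in true_times:
            i = int(t * FS)
            trace[i:i + spike.size] += spike
        det = detect_spikes(trace, FS, dvdt_threshold=10.0)
        assert det.size == 3
        assert np.all(np.abs(det - true_times) < 1e-3)

    def test_slow_sinusoid_below_threshold(self):
        # 2 Hz, 5 mV amplitude: max dV/dt = 2*pi*2*5/1000 mV/ms ~ 0.063
        t = np.arange(0, 2, 1 / FS)
        trace = -60 + 5 * np.sin(2 * np.pi * 2 * t)
        assert detect_spikes(trace, FS, dvdt_threshold=10.0).size == 0

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            detect_spikes(np.zeros(100), FS, dvdt_threshold=0.0)


class TestRemoveSpikes:
    def test_constant_unchanged(self):
        x = np.full(1000, -55.0)
        np.testing.assert_allclose(remove_spikes(x, FS), x)

    def test_linear_ramp_interior_unchanged(self):
        x = np.linspace(-70, -50, 2000)
        out = remove_spikes(x, FS)
        np.testing.assert_allclose(out[50:-50], x[50:-50], atol=1e-9)

    def test_narrow_spike_removed(self):
        rng = np.random.default_rng(1)
        base = -60 + np.cumsum(rng.normal(0, 0.01, 5000))
        trace = base.copy()
        trace[2000:2015] += 50.0  # 1.5 ms wide transient
        out = remove_spikes(trace, FS)
        assert np.max(np.abs(out - base)) < 1.0

    def test_matches_bruteforce_median(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=500)
        expected = oracles.median_filter_brute(x, 61)
        np.testing.assert_allclose(remove_spikes(x, FS), expected,
                                   rtol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            remove_spikes(np.zeros(10), FS)


class TestSmoothCurrent:
    def test_constant_unchanged(self):
        x = np.full(2000, -40.0)
        np.testing.assert_allclose(smooth_current(x, FS), x)

    def test_white_noise_sd_reduced_by_sqrt_window(self):
        rng = np.random.default_rng(3)
        sigma, w = 5.0, 400
        x = rng.normal(0, sigma, 400000)
        out = smooth_current(x, FS)
        assert np.std(out) == pytest.approx(sigma / np.sqrt(w), rel=0.10)

    def test_impulse_response_is_rectangular(self):
        x = np.zeros(2000)
        x[1000] = 1.0
        out = smooth_current(x, FS)
        nz = out[out > 0]
        assert nz.size == 400
        np.testing.assert_allclose(nz, 1.0 / 400)

    def test_matches_bruteforce_mean(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=900)
        expected = oracles.mean_filter_brute(x, 400)
        np.testing.assert_allclose(smooth_current(x, FS), expected,
                                   rtol=1e-10, atol=1e-12)


@pytest.mark.parametrize("filt,win", [(remove_spikes, None),
                                      (smooth_current, None)])
def test_filters_commute_with_additive_offset(filt, win):
    rng = np.random.default_rng(5)
    x = rng.normal(size=800)
    np.testing.assert_allclose(filt(x + 12.5, FS), filt(x, FS) + 12.5,
                               rtol=1e-9, atol=1e-9)


class TestCycleAverage:
    def _trace_with_cycle_amps(self, protocol, amps, onset=0.1):
        """Half-rectified 2 Hz sinusoid with per-cycle amplitudes."""
        n = int(round((onset + 1.7) * protocol.sampling_rate))
        t = np.arange(n) / protocol.sampling_rate
        x = np.zeros(n)
        for c, a in enumerate(amps):
            c0 = onset + c * protocol.cycle_period
            m = (t >= c0) & (t < c0 + protocol.cycle_period)
            x[m] = a * np.clip(np.sin(2 * np.pi * 2 * (t[m] - c0)), 0,
                               None)
        return x

    def test_identical_cycles_average_to_one_cycle(self, protocol):
        x = self._trace_with_cycle_amps(protocol, [1.0, 1.0, 1.0])
        ca = cycle_average(x, protocol, 0.1)
        assert ca.n_cycles_used == 3
        assert not ca.adapted
        assert ca.waveform.max() == pytest.approx(1.0, rel=1e-6)

    def test_adaptation_drops_third_cycle(self, protocol):
        x = self._trace_with_cycle_amps(protocol, [1.0, 1.0, 0.3])
        ca = cycle_average(x, protocol, 0.1,
                           adaptation_ratio_threshold=0.5)
        assert ca.n_cycles_used == 2
        assert ca.adapted
        assert ca.waveform.max() == pytest.approx(1.0, rel=1e-6)

    def test_matches_bruteforce_windows(self, protocol):
        rng = np.random.default_rng(6)
        x = rng.normal(size=int(1.8 * FS))
        ca = cycle_average(x, protocol, 0.1)
        expected, n = oracles.cycle_average_brute(
            x, FS, 0.1, 0.5, 0.05, 0.55, 3, 0.5)
        assert ca.n_cycles_used == n
        np.testing.assert_allclose(ca.waveform, expected, rtol=1e-12)

    def test_linear_in_trace_at_fixed_cycle_count(self, protocol):
        rng = np.random.default_rng(7)
        x = rng.normal(size=int(1.8 * FS))
        y = rng.normal(size=int(1.8 * FS))
        cx = cycle_average(x, protocol, 0.1, force_n_cycles=3).waveform
        cy = cycle_average(y, protocol, 0.1, force_n_cycles=3).waveform
        cxy = cycle_average(2 * x + y, protocol, 0.1,
                            force_n_cycles=3).waveform
        np.testing.assert_allclose(cxy, 2 * cx + cy, rtol=1e-9,
                                   atol=1e-12)

    def test_short_trace_rejected(self, protocol):
        with pytest.raises(ValueError):
            cycle_average(np.zeros(1000), protocol, 0.1)


class TestBaseline:
    def test_constant_blank(self):
        b = compute_baseline([np.full(15000, -60.0)], (0.0, 1.5), FS,
                             units="mV")
        assert b.mean == -60.0 and b.sd == 0.0

    def test_sinusoid_moments(self):
        t = np.arange(0, 1.5, 1 / FS)
        blank = -60 + np.sin(2 * np.pi * 2 * t)  # whole cycles
        b = compute_baseline([blank], (0.0, 1.5), FS, units="mV")
        assert b.mean == pytest.approx(-60.0, abs=0.01)
        assert b.sd == pytest.approx(1 / np.sqrt(2), rel=0.02)

    def test_two_constant_blanks_average_first(self):
        b = compute_baseline([np.full(15000, -58.0),
                              np.full(15000, -62.0)], (0.0, 1.5), FS)
        assert b.mean == -60.0 and b.sd == 0.0

    def test_no_blanks_rejected(self):
        with pytest.raises(ValueError):
            compute_baseline([], (0.0, 1.5), FS)


class TestResponseMagnitude:
    def _cat(self, w, units="mV"):
        return CycleAveragedTrace(waveform=w, n_cycles_used=3,
                                  direction=0.0, units=units)

    def test_flat_at_baseline_is_zero(self):
        avg = self._cat(np.full(5000, -60.0))
        m = response_magnitude(avg, Baseline(-60.0, 0.0, "mV"),
                               "current_clamp")
        assert m.magnitude == 0.0

    def test_vm_peak_depolarization(self):
        t = np.arange(5000) / FS
        w = -60 + 8 * np.clip(np.sin(2 * np.pi * 2 * t), 0, None)
        m = response_magnitude(self._cat(w),
                               Baseline(-60.0, 0.0, "mV"),
                               "current_clamp")
        assert m.magnitude == pytest.approx(8.0, rel=0.01)

    def test_epsc_peak_inward_reported_positive(self):
        t = np.arange(5000) / FS
        w = -10 - 40 * np.clip(np.sin(2 * np.pi * 2 * t), 0, None)
        m = response_magnitude(self._cat(w, "pA"),
                               Baseline(-10.0, 0.0, "pA"),
                               "voltage_clamp")
        assert m.magnitude == pytest.approx(40.0, rel=0.01)

    def test_invariant_to_common_offset(self):
        rng = np.random.default_rng(8)
        w = rng.normal(size=5000)
        m0 = response_magnitude(self._cat(w), Baseline(0.0, 0.0, "mV"),
                                "current_clamp")
        m1 = response_magnitude(self._cat(w + 7.0),
                                Baseline(7.0, 0.0, "mV"),
                                "current_clamp")
        assert m0.magnitude == pytest.approx(m1.magnitude, rel=1e-12)

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError):
            response_magnitude(self._cat(np.zeros(100), "pA"),
                               Baseline(0.0, 0.0, "mV"),
                               "voltage_clamp")
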