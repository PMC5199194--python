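"""Optogenetic decomposition and per-cell assembly."""

import numpy as np
import pytest

from binomatch import (GeneratorConfig, TuningCurve, analyze_dataset,
                       assemble_cell, delta_orientation, generate_cohort,
                       scale_factor, subtract_thalamic, smooth_current,
                       cycle_average)
from binomatch.preprocess import CycleAveragedTrace

DIRS = np.arange(12) * 30.0


def cat(w, direction=0.0, n=3):
    return CycleAveragedTrace(waveform=np.asarray(w, float),
                              n_cycles_used=n, direction=direction,
                              units="pA")


class TestSubtractThalamic:
    def test_zero_thalamic_leaves_total(self):
        rng = np.random.default_rng(0)
        total = rng.normal(size=5000)
        out = subtract_thalamic(cat(total), cat(np.zeros(5000)))
        np.testing.assert_allclose(out.waveform, total)
        assert out.input_type == "cortical"

    def test_equal_inputs_cancel(self):
        rng = np.random.default_rng(1)
        w = rng.normal(size=5000)
        out = subtract_thalamic(cat(w), cat(w.copy()))
        np.testing.assert_allclose(out.waveform, 0.0, atol=1e-15)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_thalamic(cat(np.zeros(100)), cat(np.zeros(99)))

    def test_direction_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_thalamic(cat(np.zeros(10), direction=0.0),
                              cat(np.zeros(10), direction=30.0))

    def test_recovers_generator_cortical_component(self, protocol):
        """In the noiseless additive model, smoothing and cycle-averaging
        are linear, so total minus thalamic must equal the cortical
        component put through the same deterministic chain."""
        cfg = GeneratorConfig.preset("adult", n_cells=1, seed=5,
                                     noise_sd=0.0)
        ds, truths = generate_cohort(cfg)
        sweeps = next(iter(ds.cells.values()))
        truth = truths[0]
        onset = cfg.stimulus_onset_s
        fs = protocol.sampling_rate
        t = np.arange(int(cfg.trace_duration_s * fs)) / fs
        env = np.clip(np.sin(2 * np.pi * 2 * (t - onset)), 0, None)
        env[(t < onset) | (t >= onset + 1.5)] = 0.0
        for eye in ("contra", "ipsi"):
            for d in DIRS:
                ta, ca = truth.component_amplitudes[(eye, float(d))]
                tot = [s.trace for s in sweeps
                       if s.eye == eye and not s.is_blank
                       and s.led == "off" and float(s.stimulus) == d]
                thal = [s.trace for s in sweeps
                        if s.eye == eye and not s.is_blank
                        and s.led == "on" and float(s.stimulus) == d]
                chain = lambda x: cycle_average(
                    smooth_current(np.mean(x, axis=0), fs), protocol,
                    onset, force_n_cycles=3).waveform
                cort = chain(tot) - chain(thal) \
                    - (cfg.hold_off_pa - cfg.hold_on_pa)
                expected = cycle_average(
                    smooth_current(-ca * env, fs), protocol, onset,
                    force_n_cycles=3).waveform
                peak = max(np.abs(expected).max(), 1.0)
                assert np.max(np.abs(cort - expected)) < 1e-9 * peak


class TestScaleFactor:
    def _curve(self, mags):
        return TuningCurve(directions=DIRS, magnitudes=mags)

    def test_identical_curves_give_one(self):
        m = np.random.default_rng(2).uniform(1, 5, 12)
        assert scale_factor(self._curve(m), self._curve(m)) == \
            pytest.approx(1.0)

    def test_proportional_curves(self):
        m = np.random.default_rng(3).uniform(1, 5, 12)
        assert scale_factor(self._curve(0.32 * m), self._curve(m)) == \
            pytest.approx(0.32)

    def test_matches_bruteforce_mean_ratio(self):
        rng = np.random.default_rng(4)
        a, b = rng.uniform(0.5, 5, 12), rng.uniform(0.5, 5, 12)
        assert scale_factor(self._curve(a), self._curve(b)) == \
            pytest.approx(np.mean(a) / np.mean(b), rel=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(5)
        a, b = rng.uniform(0.5, 5, 12), rng.uniform(0.5, 5, 12)
        s1 = scale_factor(self._curve(a), self._curve(b))
        s2 = scale_factor(self._curve(3.7 * a), self._curve(3.7 * b))
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_zero_total_flagged_as_nan(self):
        assert np.isnan(scale_factor(self._curve(np.ones(12)),
                                     self._curve(np.zeros(12))))


class TestAssembleCell:
    def test_noiseless_recovery(self, noiseless_adult_cohort, protocol):
        cfg, ds, truths = noiseless_adult_cohort
        results = analyze_dataset(ds)
        for r, t in zip(results, truths):
            for eye in ("contra", "ipsi"):
                assert delta_orientation(
                    r.pref_o(eye, "thalamic"),
                    t.pref_thalamic[eye]) < 1.0
                assert delta_orientation(
                    r.pref_o(eye, "cortical"),
                    t.pref_cortical[eye]) < 1.0
                assert r.scale_factor[eye] == pytest.approx(
                    t.scale_factor[eye], abs=0.02)
            assert abs(r.delta_o["thalamic"] - t.delta_o_thalamic) < 1.0
            assert r.ci_ratio_total == pytest.approx(cfg.ci_ratio,
                                                     rel=0.05)
            assert r.ci_ratio_thalamic == pytest.approx(cfg.ci_ratio,
                                                        rel=0.05)

    def test_matched_components_give_zero_deltas(self, protocol):
        """All preference scatter off: every difference metric is 0."""
        cfg = GeneratorConfig(
            cohort="custom", n_cells=2, seed=9, noise_sd=0.0,
            delta_o_thalamic_mean=0.0,
            thal_cort_diff_mean={"contra": 0.0, "ipsi": 0.0})
        ds, truths = generate_cohort(cfg)
        for r in analyze_dataset(ds):
            for itype in ("total", "thalamic", "cortical"):
                assert r.delta_o[itype] == pytest.approx(0.0, abs=1.0)
            for eye in ("contra", "ipsi"):
                assert r.thal_total_diff[eye] == pytest.approx(0.0,
                                                               abs=1.0)
                assert r.thal_cort_diff[eye] == pytest.approx(0.0,
                                                              abs=1.0)

    def test_missing_condition_reported(self, noiseless_adult_cohort,
                                        protocol):
        _, ds, _ = noiseless_adult_cohort
        sweeps = [s for s in next(iter(ds.cells.values()))
                  if not (s.eye == "ipsi" and not s.is_blank
                          and float(s.stimulus) == 60.0
                          and s.led == "on")]
        with pytest.raises(ValueError, match="missing condition"):
            assemble_cell(sweeps, protocol)

    def test_current_clamp_recovers_emergent_vm_preference(
            self, small_cc_cohort, protocol):
        """The Vm preference must match the vector-sum preference of the
        generator's summed (thalamic + cortical) component curve."""
        from binomatch import orientation_vector
        cfg, ds, truths = small_cc_cohort
        results = analyze_dataset(ds)
        for r, t in zip(results, truths):
            for eye in ("contra", "ipsi"):
                mags = np.array(
                    [sum(t.component_amplitudes[(eye, float(d))])
                     for d in DIRS])
                expected = orientation_vector(
                    TuningCurve(directions=DIRS, magnitudes=mags)).pref_o
                assert delta_orientation(r.pref_o(eye, "total"),
                                         expected) < 2.0
            assert ("contra", "total") in r.curves
            assert ("contra", "thalamic") not in r.curves
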