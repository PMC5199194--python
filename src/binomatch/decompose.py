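"""Optogenetic decomposition of excitation and per-cell assembly.

Total EPSCs (LED-off) and thalamic EPSCs (LED-on, cortex silenced) are each
cycle-averaged and baseline-subtracted with their own LED-matched blank
baseline; the intracortical EPSC trace is then the point-by-point
subtraction of the thalamic from the total trace.  Tuning curves, vector
orientation statistics, inter-ocular differences, the thalamic/total scale
factor and the contralateral/ipsilateral amplitude ratio are assembled per
cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from . import preprocess as pp
from .protocol import (CONTRA, CORTICAL, CURRENT_CLAMP, EYES, IPSI,
                       LED_OFF, LED_ON, THALAMIC, TOTAL, VOLTAGE_CLAMP,
                       StimulusProtocol, SweepRecord)
from .tuning import (OrientationStats, TuningCurve, build_tuning_curve,
                     delta_orientation, orientation_vector)


@dataclass(frozen=True)
class AnalysisParams:
    """Preprocessing parameters for the per-cell pipeline."""

    dvdt_threshold_mv_per_ms: float = pp.DEFAULT_DVDT_THRESHOLD
    refractory_ms: float = pp.DEFAULT_REFRACTORY_MS
    median_window_ms: float = pp.DEFAULT_MEDIAN_WINDOW_MS
    mean_window_ms: float = pp.DEFAULT_MEAN_WINDOW_MS
    adaptation_ratio_threshold: float = pp.DEFAULT_ADAPTATION_RATIO


@dataclass
class CellResult:
    """All per-cell metrics for one recorded (or simulated) neuron.

    ``curves`` and ``stats`` are keyed by (eye, input_type); current-clamp
    cells carry only the (eye, "total") entries.  Angular fields are
    degrees on the orientation cycle; None marks an undefined value
    (untuned curve), which excludes the cell from that statistic.
    """

    cell_id: str
    clamp_mode: str
    group: Optional[str] = None
    curves: Dict[tuple, TuningCurve] = field(default_factory=dict)
    stats: Dict[tuple, OrientationStats] = field(default_factory=dict)
    delta_o: Dict[str, Optional[float]] = field(default_factory=dict)
    thal_total_diff: Dict[str, Optional[float]] = field(default_factory=dict)
    thal_cort_diff: Dict[str, Optional[float]] = field(default_factory=dict)
    scale_factor: Dict[str, float] = field(default_factory=dict)
    ci_ratio_total: Optional[float] = None
    ci_ratio_thalamic: Optional[float] = None
    qc: Dict[str, object] = field(default_factory=dict)

    def pref_o(self, eye: str, input_type: str) -> Optional[float]:
        st = self.stats.get((eye, input_type))
        return None if st is None else st.pref_o


def subtract_thalamic(total_avg: pp.CycleAveragedTrace,
                      thalamic_avg: pp.CycleAveragedTrace
                      ) -> pp.CycleAveragedTrace:
    """Cortical EPSC trace: point-by-point total minus thalamic.

    Both inputs must be baseline-subtracted, cycle-averaged voltage-clamp
    waveforms for the same direction with matching length and cycle count.
    """
    if total_avg.waveform.size != thalamic_avg.waveform.size:
        raise ValueError("waveform length mismatch between total and "
                         "thalamic traces")
    if (total_avg.direction is not None and thalamic_avg.direction is not None
            and not np.isclose(total_avg.direction, thalamic_avg.direction)):
        raise ValueError(
            f"direction mismatch: total {total_avg.direction}, thalamic "
            f"{thalamic_avg.direction}")
    if total_avg.n_cycles_used != thalamic_avg.n_cycles_used:
        raise ValueError("cycle-count mismatch; recompute both traces with "
                         "the smaller cycle count first")
    return pp.CycleAveragedTrace(
        waveform=total_avg.waveform - thalamic_avg.waveform,
        n_cycles_used=total_avg.n_cycles_used,
        direction=total_avg.direction, eye=total_avg.eye,
        input_type=CORTICAL, units=total_avg.units)


def scale_factor(thalamic_curve: TuningCurve,
                 total_curve: TuningCurve) -> float:
    """Mean thalamic tuning-curve amplitude over mean total amplitude.

    The fraction of a cell's visually evoked excitation that is thalamic.
    Returns NaN (cell flagged by the caller) when the total mean is not
    positive.
    """
    if thalamic_curve.directions.size != total_curve.directions.size:
        raise ValueError("curves differ in direction count")
    total_mean = float(np.mean(total_curve.magnitudes))
    if total_mean <= 0:
        return float("nan")
    return float(np.mean(thalamic_curve.magnitudes)) / total_mean


def _group_sweeps(sweeps: Sequence[SweepRecord]):
    blanks: Dict[str, list] = {}
    conds: Dict[tuple, list] = {}
    for s in sweeps:
        if s.is_blank:
            blanks.setdefault(s.led, []).append(s.trace)
        else:
            key = (s.eye, s.led, float(s.stimulus) % 360.0)
            conds.setdefault(key, []).append(s.trace)
    return blanks, conds


def _ci_ratio(contra_curve: Optional[TuningCurve],
              ipsi_curve: Optional[TuningCurve]) -> Optional[float]:
    if contra_curve is None or ipsi_curve is None:
        return None
    denom = float(np.mean(ipsi_curve.magnitudes))
    if denom <= 0:
        return None
    return float(np.mean(contra_curve.magnitudes)) / denom


def assemble_cell(sweeps: Sequence[SweepRecord],
                  protocol: StimulusProtocol,
                  params: AnalysisParams = AnalysisParams(),
                  group: Optional[str] = None) -> CellResult:
    """Run the full per-cell pipeline on one cell's sweeps.

    Voltage-clamp cells require both eyes x both LED states x all
    directions plus blanks per LED state, and yield total/thalamic/cortical
    tuning, orientation statistics, inter-ocular differences, scale factors
    and the contra/ipsi amplitude ratio.  Current-clamp cells require
    LED-off sweeps only and yield per-eye subthreshold Vm tuning and its
    inter-ocular difference.
    """
    if not sweeps:
        raise ValueError("no sweeps given")
    cell_id = sweeps[0].cell_id
    clamp_mode = sweeps[0].clamp_mode
    fs = sweeps[0].sampling_rate
    if clamp_mode == VOLTAGE_CLAMP:
        return _assemble_voltage_clamp(cell_id, sweeps, protocol, params,
                                       fs, group)
    return _assemble_current_clamp(cell_id, sweeps, protocol, params, fs,
                                   group)


def _blank_window(sweeps: Sequence[SweepRecord],
                  protocol: StimulusProtocol) -> tuple[float, float]:
    onset = sweeps[0].stimulus_onset
    return (onset, onset + protocol.stimulus_duration)


def _assemble_voltage_clamp(cell_id, sweeps, protocol, params, fs, group):
    blanks, conds = _group_sweeps(sweeps)
    onset = next(s.stimulus_onset for s in sweeps if not s.is_blank)
    window = _blank_window(sweeps, protocol)

    baselines = {}
    for led in (LED_OFF, LED_ON):
        if led not in blanks:
            raise ValueError(f"cell {cell_id}: no blank sweeps for LED "
                             f"state {led!r}")
        smoothed = [pp.smooth_current(t, fs, params.mean_window_ms)
                    for t in blanks[led]]
        baselines[led] = pp.compute_baseline(smoothed, window, fs,
                                             units="pA")

    result = CellResult(cell_id=cell_id, clamp_mode=VOLTAGE_CLAMP,
                        group=group)
    result.qc["adapted_conditions"] = []

    for eye in EYES:
        mags = {TOTAL: [], THALAMIC: [], CORTICAL: []}
        ncyc = {TOTAL: [], THALAMIC: [], CORTICAL: []}
        for d in protocol.directions:
            avgs = {}
            for led, label in ((LED_OFF, TOTAL), (LED_ON, THALAMIC)):
                key = (eye, led, float(d))
                if key not in conds:
                    raise ValueError(
                        f"cell {cell_id}: missing condition eye={eye} "
                        f"led={led} direction={d:g}")
                raw = pp.average_sweeps(conds[key])
                sm = pp.smooth_current(raw, fs, params.mean_window_ms)
                avgs[label] = pp.cycle_average(
                    sm, protocol, onset,
                    params.adaptation_ratio_threshold,
                    direction=float(d), eye=eye, input_type=label,
                    units="pA")
                if avgs[label].adapted:
                    result.qc["adapted_conditions"].append(
                        (eye, label, float(d)))
                # keep the baseline-subtracted trace for decomposition
                led_key = led
                avgs[label].waveform = (avgs[label].waveform
                                        - baselines[led_key].mean)
            if avgs[TOTAL].n_cycles_used != avgs[THALAMIC].n_cycles_used:
                n = min(avgs[TOTAL].n_cycles_used,
                        avgs[THALAMIC].n_cycles_used)
                for led, label in ((LED_OFF, TOTAL), (LED_ON, THALAMIC)):
                    raw = pp.average_sweeps(conds[(eye, led, float(d))])
                    sm = pp.smooth_current(raw, fs, params.mean_window_ms)
                    avgs[label] = pp.cycle_average(
                        sm, protocol, onset, force_n_cycles=n,
                        direction=float(d), eye=eye, input_type=label,
                        units="pA")
                    avgs[label].waveform = (avgs[label].waveform
                                            - baselines[led].mean)
            avgs[CORTICAL] = subtract_thalamic(avgs[TOTAL], avgs[THALAMIC])
            zero = pp.Baseline(mean=0.0, sd=0.0, units="pA")
            for label in (TOTAL, THALAMIC, CORTICAL):
                mags[label].append(pp.response_magnitude(
                    avgs[label], zero, VOLTAGE_CLAMP))
                ncyc[label].append(avgs[label].n_cycles_used)
        for label in (TOTAL, THALAMIC, CORTICAL):
            led = LED_ON if label == THALAMIC else LED_OFF
            curve = build_tuning_curve(
                mags[label], baseline=baselines[led], eye=eye,
                input_type=label, clamp_mode=VOLTAGE_CLAMP,
                directions=protocol.directions,
                n_cycles_used=min(ncyc[label]))
            result.curves[(eye, label)] = curve
            result.stats[(eye, label)] = orientation_vector(curve)
        result.scale_factor[eye] = scale_factor(
            result.curves[(eye, THALAMIC)], result.curves[(eye, TOTAL)])

    for label in (TOTAL, THALAMIC, CORTICAL):
        result.delta_o[label] = delta_orientation(
            result.pref_o(CONTRA, label), result.pref_o(IPSI, label))
    for eye in EYES:
        result.thal_total_diff[eye] = delta_orientation(
            result.pref_o(eye, THALAMIC), result.pref_o(eye, TOTAL))
        result.thal_cort_diff[eye] = delta_orientation(
            result.pref_o(eye, THALAMIC), result.pref_o(eye, CORTICAL))
    result.ci_ratio_total = _ci_ratio(result.curves.get((CONTRA, TOTAL)),
                                      result.curves.get((IPSI, TOTAL)))
    result.ci_ratio_thalamic = _ci_ratio(
        result.curves.get((CONTRA, THALAMIC)),
        result.curves.get((IPSI, THALAMIC)))
    result.qc["clipped_fraction_cortical"] = float(np.mean(
        [result.curves[(eye, CORTICAL)].n_clipped / protocol.n_directions
         for eye in EYES]))
    result.qc["undefined_pref"] = sorted(
        key for key, st in result.stats.items() if not st.defined)
    return result


def _assemble_current_clamp(cell_id, sweeps, protocol, params, fs, group):
    blanks, conds = _group_sweeps(sweeps)
    onset = next(s.stimulus_onset for s in sweeps if not s.is_blank)
    window = _blank_window(sweeps, protocol)
    # Vm analysis uses LED-off blanks only
    if LED_OFF not in blanks:
        raise ValueError(f"cell {cell_id}: no LED-off blank sweeps")
    despiked_blanks = [pp.remove_spikes(t, fs, params.median_window_ms)
                       for t in blanks[LED_OFF]]
    baseline = pp.compute_baseline(despiked_blanks, window, fs, units="mV")

    result = CellResult(cell_id=cell_id, clamp_mode=CURRENT_CLAMP,
                        group=group)
    result.qc["adapted_conditions"] = []
    spike_counts = {}
    for eye in EYES:
        mags, ncyc = [], []
        for d in protocol.directions:
            key = (eye, LED_OFF, float(d))
            if key not in conds:
                raise ValueError(
                    f"cell {cell_id}: missing condition eye={eye} "
                    f"direction={d:g}")
            n_spikes = sum(
                pp.detect_spikes(t, fs, params.dvdt_threshold_mv_per_ms,
                                 params.refractory_ms).size
                for t in conds[key])
            spike_counts[(eye, float(d))] = int(n_spikes)
            despiked = [pp.remove_spikes(t, fs, params.median_window_ms)
                        for t in conds[key]]
            avg = pp.cycle_average(
                pp.average_sweeps(despiked), protocol, onset,
                params.adaptation_ratio_threshold, direction=float(d),
                eye=eye, input_type=TOTAL, units="mV")
            if avg.adapted:
                result.qc["adapted_conditions"].append((eye, TOTAL,
                                                        float(d)))
            mags.append(pp.response_magnitude(avg, baseline, CURRENT_CLAMP))
            ncyc.append(avg.n_cycles_used)
        curve = build_tuning_curve(mags, baseline=baseline, eye=eye,
                                   input_type=TOTAL,
                                   clamp_mode=CURRENT_CLAMP,
                                   directions=protocol.directions,
                                   n_cycles_used=min(ncyc))
        result.curves[(eye, TOTAL)] = curve
        result.stats[(eye, TOTAL)] = orientation_vector(curve)
    result.delta_o[TOTAL] = delta_orientation(
        result.pref_o(CONTRA, TOTAL), result.pref_o(IPSI, TOTAL))
    result.ci_ratio_total = _ci_ratio(result.curves.get((CONTRA, TOTAL)),
                                      result.curves.get((IPSI, TOTAL)))
    result.qc["spike_counts"] = spike_counts
    result.qc["undefined_pref"] = sorted(
        key for key, st in result.stats.items() if not st.defined)
    return result
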