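"""Trace preprocessing: spike handling, smoothing, cycle averaging, baselines.

The current-clamp chain detects spikes on the raw trace (for QC counts),
removes them with a 6 ms running median, and cycle-averages the subthreshold
membrane potential.  The voltage-clamp chain smooths the current trace with
a 40 ms running mean before cycle averaging.  Baselines come from blank
(gray-screen) sweeps; the blank-trace mean is subtracted from each
cycle-averaged response, and the peak of the result — depolarization peak
for Vm, peak inward current (reported positive) for EPSCs — is the response
magnitude for that stimulus direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import median_filter, uniform_filter1d

from .protocol import CURRENT_CLAMP, VOLTAGE_CLAMP, StimulusProtocol

DEFAULT_DVDT_THRESHOLD = 10.0   # mV/ms, configurable stand-in for a manual setting
DEFAULT_REFRACTORY_MS = 2.0
DEFAULT_MEDIAN_WINDOW_MS = 6.0
DEFAULT_MEAN_WINDOW_MS = 40.0
DEFAULT_ADAPTATION_RATIO = 0.5


@dataclass(frozen=True)
class Baseline:
    """Mean and SD of the across-sweep-averaged blank trace.

    ``mean`` is the Vm or Im baseline in mV or pA; ``sd`` is the SD of the
    averaged blank trace over the analysis window (the spontaneous
    fluctuation SD, chiefly meaningful for Vm).
    """

    mean: float
    sd: float
    units: str = "pA"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("baseline sd must be non-negative")


@dataclass
class CycleAveragedTrace:
    """Per-condition waveform averaged over stimulus cycles."""

    waveform: np.ndarray
    n_cycles_used: int
    direction: Optional[float] = None
    eye: Optional[str] = None
    input_type: Optional[str] = None
    units: str = "pA"
    adapted: bool = False

    def __post_init__(self) -> None:
        self.waveform = np.asarray(self.waveform, dtype=float)
        if self.n_cycles_used not in (2, 3):
            raise ValueError("n_cycles_used must be 2 or 3")


@dataclass(frozen=True)
class ResponseMagnitude:
    """Baseline-subtracted peak response for one drift direction."""

    direction: float
    magnitude: float
    units: str = "pA"

    def __post_init__(self) -> None:
        if not np.isfinite(self.magnitude):
            raise ValueError("response magnitude must be finite")


def _odd_window(window_ms: float, sampling_rate: float) -> int:
    n = int(round(window_ms / 1000.0 * sampling_rate))
    return n if n % 2 == 1 else n + 1


def detect_spikes(trace: np.ndarray, sampling_rate: float,
                  dvdt_threshold: float = DEFAULT_DVDT_THRESHOLD,
                  refractory_ms: float = DEFAULT_REFRACTORY_MS) -> np.ndarray:
    """Spike onset times from upward dV/dt threshold crossings.

    The derivative is the first difference scaled to mV/ms.  A crossing
    within ``refractory_ms`` of a previous detection is suppressed.

    Returns onset times in seconds from the start of the trace.
    """
    trace = np.asarray(trace, dtype=float)
    if dvdt_threshold <= 0:
        raise ValueError("dvdt_threshold must be positive")
    if trace.size < 2:
        raise ValueError("trace must have at least 2 samples")
    dvdt = np.diff(trace) * sampling_rate / 1000.0  # mV per ms
    above = dvdt >= dvdt_threshold
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        crossings = np.concatenate(([0], crossings))
    refractory = refractory_ms / 1000.0
    times = []
    last = -np.inf
    for idx in crossings:
        t = idx / sampling_rate
        if t - last >= refractory:
            times.append(t)
            last = t
    return np.asarray(times)


def remove_spikes(trace: np.ndarray, sampling_rate: float,
                  window_ms: float = DEFAULT_MEDIAN_WINDOW_MS) -> np.ndarray:
    """Subthreshold Vm: running median over a 6 ms window (forced odd).

    Edges are reflect-padded so the output has the input's length.
    """
    trace = np.asarray(trace, dtype=float)
    n = _odd_window(window_ms, sampling_rate)
    if trace.size < n:
        raise ValueError(
            f"trace ({trace.size} samples) shorter than the median window "
            f"({n} samples)")
    return median_filter(trace, size=n, mode="reflect")


def smooth_current(trace: np.ndarray, sampling_rate: float,
                   window_ms: float = DEFAULT_MEAN_WINDOW_MS) -> np.ndarray:
    """Smoothed Im: running mean over a 40 ms window, reflect-padded."""
    trace = np.asarray(trace, dtype=float)
    n = int(round(window_ms / 1000.0 * sampling_rate))
    if trace.size < n:
        raise ValueError(
            f"trace ({trace.size} samples) shorter than the mean window "
            f"({n} samples)")
    return uniform_filter1d(trace, size=n, mode="reflect")


def _cycle_windows(trace: np.ndarray, protocol: StimulusProtocol,
                   stimulus_onset: float) -> np.ndarray:
    fs = protocol.sampling_rate
    n = protocol.window_n_samples
    windows = []
    for k in range(protocol.n_cycles):
        onset = stimulus_onset + k * protocol.cycle_period
        i0 = int(round((onset + protocol.cycle_window_start) * fs))
        if i0 < 0 or i0 + n > trace.size:
            raise ValueError(
                f"trace too short for cycle {k + 1} window "
                f"[{i0}, {i0 + n}) of {trace.size} samples")
        windows.append(trace[i0:i0 + n])
    return np.asarray(windows)


def cycle_average(trace: np.ndarray, protocol: StimulusProtocol,
                  stimulus_onset: float,
                  adaptation_ratio_threshold: float = DEFAULT_ADAPTATION_RATIO,
                  force_n_cycles: Optional[int] = None,
                  **trace_labels) -> CycleAveragedTrace:
    """Average the 50-550 ms post-cycle-onset windows of the three cycles.

    If the third cycle's peak-to-peak amplitude falls below
    ``adaptation_ratio_threshold`` times the mean of the first two cycles'
    amplitudes, the cell is considered to adapt in the third cycle and only
    cycles 1-2 are averaged.  ``force_n_cycles`` bypasses the adaptation
    rule (used to put LED-off and LED-on traces on a common cycle count
    before subtraction).
    """
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise ValueError("trace contains non-finite samples")
    windows = _cycle_windows(trace, protocol, stimulus_onset)
    adapted = False
    if force_n_cycles is not None:
        if force_n_cycles not in (2, 3):
            raise ValueError("force_n_cycles must be 2 or 3")
        n_used = force_n_cycles
    else:
        amps = windows.max(axis=1) - windows.min(axis=1)
        first_two = 0.5 * (amps[0] + amps[1])
        adapted = bool(amps[2] < adaptation_ratio_threshold * first_two)
        n_used = 2 if adapted else 3
    waveform = windows[:n_used].mean(axis=0)
    return CycleAveragedTrace(waveform=waveform, n_cycles_used=n_used,
                              adapted=adapted, **trace_labels)


def average_sweeps(traces: Sequence[np.ndarray]) -> np.ndarray:
    """Mean across same-condition sweeps (trial averaging before cycling)."""
    if len(traces) == 0:
        raise ValueError("no sweeps to average")
    return np.mean(np.asarray(traces, dtype=float), axis=0)


def compute_baseline(blank_traces: Sequence[np.ndarray],
                     window: tuple[float, float],
                     sampling_rate: float,
                     units: str = "pA") -> Baseline:
    """Baseline mean/SD from the across-sweep-averaged blank trace.

    ``window`` is a (start, end) interval in seconds; by convention it
    spans the same duration as the stimulus period, starting at the blank
    sweep's nominal onset.
    """
    if len(blank_traces) == 0:
        raise ValueError("no blank sweeps for baseline")
    avg = average_sweeps(blank_traces)
    i0 = int(round(window[0] * sampling_rate))
    i1 = int(round(window[1] * sampling_rate))
    if not (0 <= i0 < i1 <= avg.size):
        raise ValueError(f"baseline window {window} outside trace")
    seg = avg[i0:i1]
    return Baseline(mean=float(np.mean(seg)), sd=float(np.std(seg)),
                    units=units)


def response_magnitude(avg: CycleAveragedTrace, baseline: Baseline,
                       clamp_mode: str) -> ResponseMagnitude:
    """Peak baseline-subtracted response of a cycle-averaged trace.

    Current clamp: peak depolarization above the Vm baseline.  Voltage
    clamp: peak inward (negative-going) current relative to the Im
    baseline, reported as a positive magnitude.
    """
    if avg.units != baseline.units:
        raise ValueError(
            f"unit mismatch: trace in {avg.units}, baseline in "
            f"{baseline.units}")
    resid = avg.waveform - baseline.mean
    if clamp_mode == CURRENT_CLAMP:
        mag = float(np.max(resid))
    elif clamp_mode == VOLTAGE_CLAMP:
        mag = float(np.max(-resid))
    else:
        raise ValueError(f"unknown clamp mode {clamp_mode!r}")
    return ResponseMagnitude(direction=avg.direction if avg.direction
                             is not None else np.nan,
                             magnitude=mag, units=avg.units)
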