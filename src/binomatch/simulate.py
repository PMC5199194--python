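"""Synthetic intracellular recordings with known ground truth.

Each simulated layer-4 cell receives, per eye, a tuned thalamic and a tuned
intracortical excitatory component.  Component tuning is a von-Mises-style
bump on the 180 deg orientation cycle with a baseline offset; the thalamic
fraction of the total excitation is the eye's scale factor, and the
contralateral eye is stronger than the ipsilateral by the ocular-dominance
ratio.  A sweep's evoked waveform is the component amplitude times a
half-rectified 2 Hz sinusoid over the three grating cycles (thalamic and
cortical components share the response phase, so the peak of the sum equals
the sum of the peaks and the linear decomposition is exact in the noiseless
case), riding on a holding baseline plus white Gaussian noise.  LED-on
sweeps contain the thalamic component only; blank sweeps are baseline plus
noise.  Current-clamp cells map the summed input to a depolarization and
inject stereotyped 1.5 ms spike waveforms while the noiseless Vm exceeds a
threshold, recording the injection times as ground truth.

Inter-ocular and thalamic-cortical preference differences are drawn from
zero-mean normals whose scales are calibrated so that the analytic mean of
the wrapped absolute difference (on [0, 90] deg) matches the cohort preset;
a preset mean at or above 45 deg is indistinguishable from unrelated
preferences and is realized as an independent uniform draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Tuple

import numpy as np
from scipy import integrate, optimize
from scipy.stats import norm

from .protocol import (BLANK, CONTRA, CURRENT_CLAMP, EYES, IPSI, LED_OFF,
                       LED_ON, VOLTAGE_CLAMP, Dataset, StimulusProtocol,
                       SweepRecord)
from .tuning import wrap_orientation

#: mean absolute wrapped difference of two unrelated orientations
UNIFORM_DELTA_MEAN = 45.0

# Cohort presets: target means (degrees) of the inter-ocular thalamic
# difference and of the per-eye thalamic-cortical differences, thalamic
# scale factors, and standard cohort sizes.
COHORT_PRESETS = {
    "adult": dict(
        delta_o_thalamic_mean=19.6,
        thal_cort_diff_mean={CONTRA: 17.0, IPSI: 22.4},
        scale_factors={CONTRA: 0.32, IPSI: 0.32},
        n_cells_vc=15, n_cells_cc=14,
    ),
    "young": dict(
        delta_o_thalamic_mean=30.9,
        thal_cort_diff_mean={CONTRA: 35.8, IPSI: 49.0},
        scale_factors={CONTRA: 0.43, IPSI: 0.52},
        n_cells_vc=26, n_cells_cc=25,
    ),
}


def folded_delta_mean(sigma: float) -> float:
    """Analytic mean of min(|x| mod 180, 180 - |x| mod 180), x ~ N(0, sigma).

    This is the expected measured orientation difference when one
    preference is the other plus zero-mean normal jitter.  Monotone in
    sigma, saturating at 45 deg (unrelated preferences).
    """
    if sigma <= 0:
        return 0.0
    if not np.isfinite(sigma):
        return UNIFORM_DELTA_MEAN

    def fold(x):
        d = np.mod(x, 180.0)
        return np.minimum(d, 180.0 - d)

    upper = max(8.0 * sigma, 180.0)
    edges = np.arange(0.0, upper + 90.0, 90.0)
    total = 0.0
    for a, b in zip(edges[:-1], edges[1:]):
        val, _ = integrate.quad(
            lambda x: fold(x) * 2.0 * norm.pdf(x, scale=sigma), a, b)
        total += val
    return total


@lru_cache(maxsize=64)
def sigma_for_delta_mean(target_mean: float) -> float:
    """Invert :func:`folded_delta_mean`: the normal scale whose wrapped
    absolute difference has the given mean.

    Returns ``inf`` for targets at or above the uniform limit of 45 deg
    (the draw then falls back to an independent uniform preference).
    """
    if target_mean < 0:
        raise ValueError("target mean must be non-negative")
    if target_mean == 0:
        return 0.0
    if target_mean >= UNIFORM_DELTA_MEAN - 0.05:
        return float("inf")
    return float(optimize.brentq(
        lambda s: folded_delta_mean(s) - target_mean, 1e-3, 150.0))


@dataclass(frozen=True)
class GeneratorConfig:
    """All knobs of the synthetic-experiment generator.

    Angular scales are calibrated from cohort preset means via
    :func:`sigma_for_delta_mean`.  ``noise_sd`` is the white-noise SD per
    10 kHz sample (pA in voltage clamp, mV in current clamp).
    """

    cohort: str = "custom"
    n_cells: int = 10
    seed: int = 0
    clamp_mode: str = VOLTAGE_CLAMP
    delta_o_thalamic_mean: float = 20.0
    thal_cort_diff_mean: Dict[str, float] = field(
        default_factory=lambda: {CONTRA: 15.0, IPSI: 15.0})
    scale_factors: Dict[str, float] = field(
        default_factory=lambda: {CONTRA: 0.35, IPSI: 0.35})
    ci_ratio: float = 2.0
    amplitude_median_pa: float = 100.0
    amplitude_sigma_ln: float = 0.3
    kappa: float = 2.0
    tuning_offset: float = 0.1
    noise_sd: float = 15.0
    n_trials: int = 2
    n_blanks: int = 2
    stimulus_onset_s: float = 0.2
    trace_duration_s: float = 1.8
    # current-clamp mapping
    vm_mv_per_pa: float = 0.15
    rest_mv: float = -60.0
    spike_threshold_mv: float = -48.0
    spike_height_mv: float = 85.0
    spike_width_ms: float = 1.5
    spike_rate_hz: float = 50.0
    # voltage-clamp holding currents (LED-on differs: tonic inhibition)
    hold_off_pa: float = -40.0
    hold_on_pa: float = -120.0
    phase_jitter_sd_s: float = 0.0

    def __post_init__(self) -> None:
        if self.ci_ratio <= 0:
            raise ValueError("ci_ratio must be positive")
        for eye, s in self.scale_factors.items():
            if not 0 < s <= 1:
                raise ValueError(f"scale factor for {eye} must be in (0, 1]")
        if self.n_cells < 0 or self.n_trials < 1 or self.n_blanks < 1:
            raise ValueError("invalid cell/trial/blank counts")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    @classmethod
    def preset(cls, cohort: str, clamp_mode: str = VOLTAGE_CLAMP,
               n_cells: Optional[int] = None, seed: int = 0,
               **overrides) -> "GeneratorConfig":
        """Cohort preset ('young' or 'adult') with standard sample sizes."""
        if cohort not in COHORT_PRESETS:
            raise ValueError(f"unknown cohort {cohort!r}; choose from "
                             f"{sorted(COHORT_PRESETS)}")
        p = COHORT_PRESETS[cohort]
        if n_cells is None:
            n_cells = (p["n_cells_vc"] if clamp_mode == VOLTAGE_CLAMP
                       else p["n_cells_cc"])
        kwargs = dict(
            cohort=cohort, n_cells=n_cells, seed=seed,
            clamp_mode=clamp_mode,
            delta_o_thalamic_mean=p["delta_o_thalamic_mean"],
            thal_cort_diff_mean=dict(p["thal_cort_diff_mean"]),
            scale_factors=dict(p["scale_factors"]),
        )
        if clamp_mode == CURRENT_CLAMP and "noise_sd" not in overrides:
            kwargs["noise_sd"] = 2.0  # mV per sample
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def analytic_delta_o_thalamic_mean(self) -> float:
        """Expected inter-ocular thalamic difference under this config."""
        return folded_delta_mean(
            sigma_for_delta_mean(self.delta_o_thalamic_mean))


@dataclass
class CellGroundTruth:
    """Generator truth for one cell; written beside the dataset, never
    read by the analysis pipeline."""

    cell_id: str
    clamp_mode: str
    pref_thalamic: Dict[str, float] = field(default_factory=dict)
    pref_cortical: Dict[str, float] = field(default_factory=dict)
    amplitude_pa: Dict[str, float] = field(default_factory=dict)
    scale_factor: Dict[str, float] = field(default_factory=dict)
    delta_o_thalamic: float = 0.0
    component_amplitudes: Dict[tuple, Tuple[float, float]] = field(
        default_factory=dict)  # (eye, direction) -> (thalamic, cortical) pA
    spike_times: Dict[tuple, np.ndarray] = field(default_factory=dict)


def tune(directions: np.ndarray, pref: float, kappa: float,
         offset: float) -> np.ndarray:
    """Orientation tuning profile, peak-normalized to 1.

    A von-Mises-style bump on the 180 deg cycle,
    ``(exp(kappa * (cos(2 * (theta - pref)) - 1)) + offset) / (1 + offset)``.
    """
    d = np.radians(np.asarray(directions, dtype=float) - pref)
    return (np.exp(kappa * (np.cos(2.0 * d) - 1.0)) + offset) / (1.0 + offset)


def _envelope(n_samples: int, protocol: StimulusProtocol, onset: float,
              phase_shift: float = 0.0) -> np.ndarray:
    """Half-rectified 2 Hz sinusoid over the stimulus period, 0 elsewhere."""
    t = np.arange(n_samples) / protocol.sampling_rate
    env = np.sin(2.0 * np.pi * protocol.temporal_frequency
                 * (t - onset - phase_shift))
    env[(t < onset) | (t >= onset + protocol.stimulus_duration)] = 0.0
    return np.clip(env, 0.0, None)


def _draw_shifted_pref(rng: np.random.Generator, base: float,
                       sigma: float) -> float:
    """A preference at normal jitter (scale sigma) from ``base``; an
    independent uniform draw when sigma is infinite."""
    if not np.isfinite(sigma):
        return float(rng.uniform(-90.0, 90.0))
    return wrap_orientation(base + rng.normal(0.0, sigma))


def _spike_waveform(config: GeneratorConfig, fs: float) -> np.ndarray:
    n = max(3, int(round(config.spike_width_ms / 1000.0 * fs)))
    rise = max(1, n // 3)
    shape = np.concatenate([np.linspace(0, 1, rise, endpoint=False),
                            np.linspace(1, 0, n - rise)])
    return config.spike_height_mv * shape


def generate_cell(config: GeneratorConfig, protocol: StimulusProtocol,
                  cell_index: int
                  ) -> Tuple[List[SweepRecord], CellGroundTruth]:
    """Simulate all sweeps of one cell plus its ground-truth record.

    The cell's random stream is derived deterministically from
    ``(config.seed, cell_index)``.
    """
    rng = np.random.default_rng([config.seed, cell_index])
    fs = protocol.sampling_rate
    n_samples = int(round(config.trace_duration_s * fs))
    onset = config.stimulus_onset_s
    cell_id = f"cell{cell_index:03d}"
    cc = config.clamp_mode == CURRENT_CLAMP

    sigma_do = sigma_for_delta_mean(config.delta_o_thalamic_mean)
    pref_thal = {CONTRA: float(rng.uniform(-90.0, 90.0))}
    pref_thal[IPSI] = _draw_shifted_pref(rng, pref_thal[CONTRA], sigma_do)
    pref_cort = {}
    for eye in EYES:
        sig = sigma_for_delta_mean(config.thal_cort_diff_mean[eye])
        pref_cort[eye] = _draw_shifted_pref(rng, pref_thal[eye], sig)

    amp_contra = float(config.amplitude_median_pa
                       * np.exp(rng.normal(0.0, config.amplitude_sigma_ln)))
    amplitude = {CONTRA: amp_contra, IPSI: amp_contra / config.ci_ratio}

    truth = CellGroundTruth(
        cell_id=cell_id, clamp_mode=config.clamp_mode,
        pref_thalamic=pref_thal, pref_cortical=pref_cort,
        amplitude_pa=amplitude, scale_factor=dict(config.scale_factors),
        delta_o_thalamic=float(
            min(abs(pref_thal[CONTRA] - pref_thal[IPSI]) % 180.0,
                180.0 - abs(pref_thal[CONTRA] - pref_thal[IPSI]) % 180.0)))

    # ground-truth preferences are orientations (pref_O convention); the
    # corresponding drift-direction peak is the orientation + 90 deg
    dirs = protocol.directions
    for eye in EYES:
        s = config.scale_factors[eye]
        t_amp = amplitude[eye] * s * tune(dirs, pref_thal[eye] + 90.0,
                                          config.kappa, config.tuning_offset)
        c_amp = amplitude[eye] * (1.0 - s) * tune(
            dirs, pref_cort[eye] + 90.0, config.kappa, config.tuning_offset)
        for d, ta, ca in zip(dirs, t_amp, c_amp):
            truth.component_amplitudes[(eye, float(d))] = (float(ta),
                                                           float(ca))

    sweeps: List[SweepRecord] = []

    def noise():
        return (rng.normal(0.0, config.noise_sd, n_samples)
                if config.noise_sd > 0 else np.zeros(n_samples))

    def phase_shift():
        return (rng.normal(0.0, config.phase_jitter_sd_s)
                if config.phase_jitter_sd_s > 0 else 0.0)

    spike_shape = _spike_waveform(config, fs) if cc else None

    led_states = (LED_OFF,) if cc else (LED_OFF, LED_ON)
    for eye in EYES:
        for d in dirs:
            ta, ca = truth.component_amplitudes[(eye, float(d))]
            for led in led_states:
                for trial in range(config.n_trials):
                    env = _envelope(n_samples, protocol, onset,
                                    phase_shift())
                    if cc:
                        depol = config.vm_mv_per_pa * (ta + ca)
                        clean = config.rest_mv + depol * env
                        trace = clean + noise()
                        times = _inject_spikes(trace, clean, config, fs,
                                               spike_shape)
                        truth.spike_times[(eye, float(d), trial)] = times
                    else:
                        hold = (config.hold_off_pa if led == LED_OFF
                                else config.hold_on_pa)
                        amp = ta + ca if led == LED_OFF else ta
                        trace = hold - amp * env + noise()
                    sweeps.append(SweepRecord(
                        cell_id=cell_id, clamp_mode=config.clamp_mode,
                        eye=eye, led=led, stimulus=float(d),
                        trial_index=trial, trace=trace,
                        stimulus_onset=onset, sampling_rate=fs))
    # blank sweeps per LED state
    for led in led_states:
        for trial in range(config.n_blanks):
            if cc:
                trace = config.rest_mv + noise()
            else:
                hold = (config.hold_off_pa if led == LED_OFF
                        else config.hold_on_pa)
                trace = hold + noise()
            sweeps.append(SweepRecord(
                cell_id=cell_id, clamp_mode=config.clamp_mode,
                eye=CONTRA, led=led, stimulus=BLANK, trial_index=trial,
                trace=trace, stimulus_onset=onset, sampling_rate=fs))
    return sweeps, truth


def _inject_spikes(trace: np.ndarray, clean: np.ndarray,
                   config: GeneratorConfig, fs: float,
                   shape: np.ndarray) -> np.ndarray:
    """Add stereotyped spike waveforms wherever the noiseless Vm is above
    threshold, at the configured firing rate; returns injection times."""
    above = clean >= config.spike_threshold_mv
    step = max(1, int(round(fs / config.spike_rate_hz)))
    times = []
    i = 0
    n = trace.size
    while i < n:
        if above[i]:
            end = min(i + shape.size, n)
            trace[i:end] += shape[:end - i]
            times.append(i / fs)
            i += step
        else:
            i += 1
    return np.asarray(times)


def generate_cohort(config: GeneratorConfig,
                    protocol: Optional[StimulusProtocol] = None
                    ) -> Tuple[Dataset, List[CellGroundTruth]]:
    """A complete synthetic experiment: Dataset plus per-cell ground truth."""
    if protocol is None:
        protocol = StimulusProtocol()
    cells: Dict[str, List[SweepRecord]] = {}
    truths: List[CellGroundTruth] = []
    for i in range(config.n_cells):
        sweeps, truth = generate_cell(config, protocol, i)
        cells[truth.cell_id] = sweeps
        truths.append(truth)
    ds = Dataset(protocol=protocol, cells=cells,
                 provenance={"generator": "binomatch.simulate",
                             "cohort": config.cohort,
                             "clamp_mode": config.clamp_mode,
                             "seed": config.seed,
                             "n_cells": config.n_cells,
                             "noise_sd": config.noise_sd})
    return ds, truths


def random_preference_pairs(n: int, seed: int = 0) -> np.ndarray:
    """n pairs of independent Uniform[-90, 90) preferred orientations."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.uniform(-90.0, 90.0, size=(n, 2))


def mean_direction_response(config: GeneratorConfig) -> float:
    """Expected tuning-curve magnitude averaged over the direction grid,
    for the median-amplitude cell's total input (pA)."""
    dirs = np.arange(12) * 30.0
    m = float(np.mean(tune(dirs, 0.0, config.kappa, config.tuning_offset)))
    return config.amplitude_median_pa * m


def noise_sd_for_magnitude_snr(config: GeneratorConfig,
                               protocol: StimulusProtocol,
                               snr: float,
                               mean_window_ms: float = 40.0) -> float:
    """White-noise SD giving a target per-direction magnitude SNR.

    The magnitude estimate averages the noise over the smoothing window,
    the trials, and the cycles, so its SD is roughly
    ``noise_sd / sqrt(W * n_trials * n_cycles)``; the SNR is the mean
    per-direction total magnitude divided by that SD.
    """
    w = int(round(mean_window_ms / 1000.0 * protocol.sampling_rate))
    reduction = np.sqrt(w * config.n_trials * protocol.n_cycles)
    return mean_direction_response(config) * reduction / snr
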