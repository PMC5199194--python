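"""Stimulus protocol and the sweep-level data model.

A recording session presents drifting sinusoidal gratings at 12 directions
(30 deg apart) to one eye at a time, each stimulus lasting 1.5 s at a
temporal frequency of 2 Hz (three grating cycles).  Intracellular traces are
sampled at 10 kHz in either current clamp (membrane potential, mV) or
voltage clamp at the inhibitory reversal potential (EPSCs, pA).  Cortical
silencing by LED photoactivation of inhibitory interneurons is encoded as a
per-sweep ``led`` label: LED-off sweeps carry the total excitation, LED-on
sweeps the isolated thalamic excitation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

import numpy as np

CONTRA = "contra"
IPSI = "ipsi"
EYES = (CONTRA, IPSI)

LED_OFF = "off"
LED_ON = "on"
LED_STATES = (LED_OFF, LED_ON)

CURRENT_CLAMP = "current_clamp"
VOLTAGE_CLAMP = "voltage_clamp"
CLAMP_MODES = (CURRENT_CLAMP, VOLTAGE_CLAMP)

BLANK = "blank"

#: input types produced by the optogenetic decomposition
TOTAL = "total"
THALAMIC = "thalamic"
CORTICAL = "cortical"
INPUT_TYPES = (TOTAL, THALAMIC, CORTICAL)


class ProtocolError(ValueError):
    """Raised when a protocol or sweep violates the data model."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Drifting-grating protocol parameters.

    The defaults describe the standard protocol: 12 drift directions at 30
    deg spacing, 1.5 s stimuli at 2 cycles/s (three cycles), responses
    cycle-averaged over a window from 50 to 550 ms after each cycle onset,
    traces sampled at 10 kHz.  ``spatial_frequency`` is metadata only.
    """

    n_directions: int = 12
    direction_step: float = 30.0
    stimulus_duration: float = 1.5
    temporal_frequency: float = 2.0
    n_cycles: int = 3
    cycle_window_start: float = 0.050
    cycle_window_end: float = 0.550
    spatial_frequency: float = 0.02
    sampling_rate: float = 10000.0

    def __post_init__(self) -> None:
        if not np.isclose(self.n_directions * self.direction_step, 360.0):
            raise ProtocolError("n_directions * direction_step must equal 360")
        if not np.isclose(self.n_cycles / self.temporal_frequency,
                          self.stimulus_duration):
            raise ProtocolError(
                "n_cycles / temporal_frequency must equal stimulus_duration")
        if not np.isclose(self.cycle_window_end - self.cycle_window_start,
                          1.0 / self.temporal_frequency):
            raise ProtocolError(
                "cycle window must span exactly one stimulus cycle")
        if self.sampling_rate <= 0:
            raise ProtocolError("sampling_rate must be positive")

    @property
    def directions(self) -> np.ndarray:
        """The drift-direction grid in degrees, ascending."""
        return np.arange(self.n_directions) * self.direction_step

    @property
    def cycle_period(self) -> float:
        """Duration of one grating cycle in seconds."""
        return 1.0 / self.temporal_frequency

    @property
    def window_n_samples(self) -> int:
        """Number of samples in one cycle-average window."""
        return int(round((self.cycle_window_end - self.cycle_window_start)
                         * self.sampling_rate))

    def validate_direction(self, direction: float) -> float:
        d = float(direction) % 360.0
        if not np.any(np.isclose(self.directions, d)):
            raise ProtocolError(
                f"direction {direction} is not on the protocol grid "
                f"(multiples of {self.direction_step} deg)")
        return d

    def to_dict(self) -> dict:
        return {
            "n_directions": self.n_directions,
            "direction_step": self.direction_step,
            "stimulus_duration": self.stimulus_duration,
            "temporal_frequency": self.temporal_frequency,
            "n_cycles": self.n_cycles,
            "cycle_window_start": self.cycle_window_start,
            "cycle_window_end": self.cycle_window_end,
            "spatial_frequency": self.spatial_frequency,
            "sampling_rate": self.sampling_rate,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusProtocol":
        return cls(**d)


@dataclass
class SweepRecord:
    """One labeled intracellular trace.

    ``stimulus`` is a drift direction in degrees (a multiple of the protocol
    step) or the string ``"blank"`` for a gray-screen sweep.  ``trace`` holds
    raw, unfiltered samples: mV in current clamp, pA in voltage clamp
    (inward currents negative).
    """

    cell_id: str
    clamp_mode: str
    eye: str
    led: str
    stimulus: Union[float, str]
    trial_index: int
    trace: np.ndarray
    stimulus_onset: float
    sampling_rate: float

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=float)
        if self.clamp_mode not in CLAMP_MODES:
            raise ProtocolError(f"unknown clamp_mode {self.clamp_mode!r}")
        if self.eye not in EYES:
            raise ProtocolError(f"unknown eye label {self.eye!r}")
        if self.led not in LED_STATES:
            raise ProtocolError(f"unknown LED state {self.led!r}")

    @property
    def is_blank(self) -> bool:
        return isinstance(self.stimulus, str) and self.stimulus == BLANK

    @property
    def units(self) -> str:
        return "mV" if self.clamp_mode == CURRENT_CLAMP else "pA"

    def validate(self, protocol: StimulusProtocol) -> None:
        if not self.is_blank:
            protocol.validate_direction(float(self.stimulus))
        needed = self.stimulus_onset + protocol.stimulus_duration
        if self.trace.size / self.sampling_rate < needed:
            raise ProtocolError(
                f"sweep of cell {self.cell_id} too short: trace covers "
                f"{self.trace.size / self.sampling_rate:.3f} s, stimulus "
                f"ends at {needed:.3f} s")


@dataclass
class Dataset:
    """A protocol plus per-cell collections of sweeps, with provenance."""

    protocol: StimulusProtocol
    cells: dict = field(default_factory=dict)  # cell_id -> list[SweepRecord]
    provenance: dict = field(default_factory=dict)

    def validate(self) -> None:
        for cell_id, sweeps in self.cells.items():
            if not sweeps:
                raise ProtocolError(f"cell {cell_id} has no sweeps")
            modes = {s.clamp_mode for s in sweeps}
            if len(modes) > 1:
                raise ProtocolError(
                    f"cell {cell_id} mixes clamp modes {sorted(modes)}")
            rates = {s.sampling_rate for s in sweeps}
            if len(rates) > 1:
                raise ProtocolError(
                    f"cell {cell_id} mixes sampling rates {sorted(rates)}")
            for s in sweeps:
                s.validate(self.protocol)
            leds = {s.led for s in sweeps if not s.is_blank}
            for led in leds:
                if not any(s.is_blank and s.led == led for s in sweeps):
                    raise ProtocolError(
                        f"cell {cell_id} has no blank sweep for LED "
                        f"state {led!r}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_sweeps(self) -> int:
        return sum(len(v) for v in self.cells.values())
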