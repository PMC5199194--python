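"""Orientation tuning curves and circular orientation statistics.

The tuning statistic is the normalized orientation vector sum

    resultant = sum_theta R(theta) * exp(2i * theta) / sum_theta R(theta)

over the 12 drift directions.  Its modulus is the global orientation
selectivity index (gOSI, in [0, 1]); half its phase, shifted by -90 deg and
wrapped into [-90, 90), is the preferred orientation (pref_O).  Inter-ocular
or inter-input preference differences are measured along the 180 deg
orientation cycle, giving values in [0, 90] deg.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .preprocess import Baseline, ResponseMagnitude


@dataclass
class TuningCurve:
    """Baseline-subtracted response magnitudes over the direction grid."""

    directions: np.ndarray
    magnitudes: np.ndarray
    baseline: Optional[Baseline] = None
    eye: Optional[str] = None
    input_type: Optional[str] = None
    clamp_mode: Optional[str] = None
    units: str = "pA"
    n_cycles_used: Optional[int] = None

    def __post_init__(self) -> None:
        self.directions = np.asarray(self.directions, dtype=float)
        self.magnitudes = np.asarray(self.magnitudes, dtype=float)
        if self.directions.shape != self.magnitudes.shape:
            raise ValueError("directions and magnitudes differ in length")

    @property
    def n_clipped(self) -> int:
        """Number of directions whose magnitude is negative (clipped to 0
        before the vector sum)."""
        return int(np.sum(self.magnitudes < 0))


@dataclass(frozen=True)
class OrientationStats:
    """gOSI and preferred orientation from the complex vector sum.

    ``pref_o`` is None (undefined) when the clipped responses sum to zero
    or the resultant has zero modulus; such cells are excluded from
    difference and correlation statistics.
    """

    gosi: float
    pref_o: Optional[float]
    resultant: complex

    @property
    def defined(self) -> bool:
        return self.pref_o is not None


def wrap_orientation(angle: float) -> float:
    """Wrap an orientation in degrees into [-90, 90)."""
    return float((np.asarray(angle) + 90.0) % 180.0 - 90.0)


def orientation_vector(curve: TuningCurve) -> OrientationStats:
    """Vector-sum orientation statistics of a tuning curve.

    Negative magnitudes are clipped to zero so the vector sum has
    non-negative weights.
    """
    r = np.clip(curve.magnitudes, 0.0, None)
    total = r.sum()
    if total <= 0:
        return OrientationStats(gosi=0.0, pref_o=None, resultant=0j)
    theta = np.radians(curve.directions)
    resultant = complex(np.sum(r * np.exp(2j * theta)) / total)
    gosi = abs(resultant)
    if gosi < 1e-12:  # numerically zero resultant: untuned
        return OrientationStats(gosi=0.0, pref_o=None, resultant=resultant)
    half_phase = np.degrees(np.angle(resultant)) / 2.0
    pref = wrap_orientation(half_phase - 90.0)
    return OrientationStats(gosi=float(gosi), pref_o=pref,
                            resultant=resultant)


def delta_orientation(pref_a: Optional[float],
                      pref_b: Optional[float]) -> Optional[float]:
    """Absolute preference difference along the 180 deg cycle, in [0, 90].

    Propagates None: if either preference is undefined the difference is
    undefined and the cell drops out of difference statistics.
    """
    if pref_a is None or pref_b is None:
        return None
    d = abs(pref_a - pref_b) % 180.0
    return float(min(d, 180.0 - d))


def build_tuning_curve(magnitudes: Sequence[ResponseMagnitude],
                       baseline: Optional[Baseline] = None,
                       eye: Optional[str] = None,
                       input_type: Optional[str] = None,
                       clamp_mode: Optional[str] = None,
                       directions: Optional[np.ndarray] = None,
                       n_cycles_used: Optional[int] = None) -> TuningCurve:
    """Assemble a TuningCurve from per-direction magnitudes.

    Requires exactly one magnitude per protocol direction; the curve is
    returned with directions sorted ascending.
    """
    if directions is None:
        directions = np.arange(12) * 30.0
    directions = np.asarray(directions, dtype=float)
    by_dir = {}
    for m in magnitudes:
        d = float(m.direction) % 360.0
        if d in by_dir:
            raise ValueError(f"duplicate magnitude for direction {d}")
        by_dir[d] = m
    missing = [d for d in directions if d not in by_dir]
    if missing:
        raise ValueError(f"missing directions: {missing}")
    extra = set(by_dir) - set(directions.tolist())
    if extra:
        raise ValueError(f"unexpected directions: {sorted(extra)}")
    mags = np.array([by_dir[d].magnitude for d in directions])
    units = {m.units for m in magnitudes}
    if len(units) > 1:
        raise ValueError(f"mixed units in magnitudes: {sorted(units)}")
    return TuningCurve(directions=directions, magnitudes=mags,
                       baseline=baseline, eye=eye, input_type=input_type,
                       clamp_mode=clamp_mode, units=units.pop(),
                       n_cycles_used=n_cycles_used)
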