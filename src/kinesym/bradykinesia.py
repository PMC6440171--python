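"""Core-bradykinesia scoring from the 10 s pronation–supination (RAM) trial.

The forearm gyroscope axis with maximal variance is taken as the rotation
axis (suit axis conventions are not assumed).  Cycle boundaries are
positive-going zero crossings of the low-pass filtered (10 Hz) angular
velocity, with crossings closer than 100 ms merged; the trial score is the
mean over cycles of the maximal absolute angular velocity.  A lower score
means more bradykinetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import Recording, SensorLayout, TaskAnnotation
from .spectral import lowpass

#: crossings closer than this are treated as one (hysteresis against noise)
MIN_CROSSING_GAP_S = 0.1
LOWPASS_CUTOFF_HZ = 10.0


@dataclass
class RamResult:
    cycle_boundaries: np.ndarray
    per_cycle_vmax: np.ndarray
    score: float
    n_cycles: int
    valid: bool
    axis: int | None = None
    sensor: str | None = None


def segment_ram_cycles(omega: np.ndarray, rate: float) -> np.ndarray:
    """Cycle-boundary sample indices of a pronation–supination velocity trace.

    Boundaries are positive-going zero crossings; crossings closer than
    100 ms to the previous kept one are merged.  A leading or trailing
    stretch covering at least half the median cycle is closed at the series
    edge, so a trial that starts or ends mid-cycle keeps those cycles.
    Fewer than 2 boundaries means the trial has no measurable cycles.
    """
    omega = np.asarray(omega, dtype=float)
    n = len(omega)
    rising = np.where((omega[:-1] <= 0) & (omega[1:] > 0))[0] + 1

    min_gap = int(round(MIN_CROSSING_GAP_S * rate))
    boundaries: list[int] = []
    for idx in rising:
        if not boundaries or idx - boundaries[-1] >= min_gap:
            boundaries.append(int(idx))
    if len(boundaries) >= 2:
        median_cycle = float(np.median(np.diff(boundaries)))
        # leading/trailing stretches covering at least half a typical cycle
        # close the first/last cycle at the series edges
        if boundaries[0] >= 0.5 * median_cycle:
            boundaries.insert(0, 0)
        if (n - boundaries[-1]) >= 0.5 * median_cycle:
            boundaries.append(n)
    return np.asarray(boundaries, dtype=int)


def ram_score(
    omega: np.ndarray, rate: float, apply_lowpass: bool = True,
    per_half_cycle: bool = False,
) -> RamResult:
    """Mean per-cycle maximal |angular velocity| of one RAM trace.

    ``per_half_cycle`` additionally splits each pronation–supination cycle at
    the negative-going crossing, yielding one maximum per half cycle.
    """
    omega = np.asarray(omega, dtype=float)
    if apply_lowpass and rate > 2.0 * LOWPASS_CUTOFF_HZ:
        omega = lowpass(omega, LOWPASS_CUTOFF_HZ, rate)
    boundaries = segment_ram_cycles(omega, rate)
    if len(boundaries) < 2:
        return RamResult(boundaries, np.empty(0), float("nan"), 0, False)

    if per_half_cycle:
        halves = segment_ram_cycles(-omega, rate)
        boundaries = np.unique(np.concatenate([boundaries, halves]))
    vmax = np.array(
        [np.max(np.abs(omega[a:b])) for a, b in zip(boundaries[:-1], boundaries[1:])]
    )
    return RamResult(
        cycle_boundaries=boundaries,
        per_cycle_vmax=vmax,
        score=float(np.mean(vmax)),
        n_cycles=len(vmax),
        valid=True,
    )


def select_rotation_axis(gyro: np.ndarray) -> int:
    """Gyro axis carrying the most variance — the pronation–supination axis."""
    return int(np.argmax(np.var(np.asarray(gyro, dtype=float), axis=0)))


def ram_task(
    recording: Recording,
    annotation: TaskAnnotation,
    layout: SensorLayout,
    sensor: str | None = None,
) -> RamResult:
    """RAM score of one trial.

    Without an explicit ``sensor``, the forearm sensor with the larger total
    gyro variance is used (the patient performs the task with one arm).
    """
    seg = recording.slice(annotation.start_s, annotation.end_s)
    if sensor is None:
        sensor = max(
            layout.forearm_sensors, key=lambda s: float(np.var(seg.gyro[s]))
        )
    gyro = seg.gyro[sensor]
    axis = select_rotation_axis(gyro)
    result = ram_score(gyro[:, axis], seg.sampling_rate)
    result.axis = axis
    result.sensor = sensor
    return result


def mean_ram_score(results: list[RamResult]) -> float:
    """Arithmetic mean over repeated trials, ignoring invalid ones."""
    scores = [r.score for r in results if r.valid]
    return float(np.mean(scores)) if scores else float("nan")
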