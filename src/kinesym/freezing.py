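"""Freezing-of-gait detection via the freeze-index power ratio.

The freeze index (FI) of a sliding window is the ratio of accelerometer
spectral power in the freeze band (3–8 Hz, leg trembling) to power in the
locomotor band (0.5–3 Hz, walking), computed on the per-frame magnitude of
the 3-axis linear acceleration of each of the 7 gait sensors (feet, shanks,
thighs, hip — the hip being the lowest trunk placement).  A time step is
frozen when the FI exceeds the threshold on at least 4 of the 7 sensors;
the task statistic is the percent of steps frozen within the walking
annotation.

Windows are centred on a 0.5 s step grid spanning the full annotation and
truncated at its edges, so the step grid covers the same time base as the
annotation itself.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Recording, SensorLayout, TaskAnnotation
from .spectral import psd

#: locomotor power below this (absolute, and relative to freeze power)
#: makes the ratio meaningless; such windows get an infinite FI.
_POWER_FLOOR = 1e-15


@dataclass(frozen=True)
class FreezeConfig:
    freeze_band: tuple[float, float] = (3.0, 8.0)
    locomotor_band: tuple[float, float] = (0.5, 3.0)
    window_s: float = 6.0
    step_s: float = 0.5
    #: FI threshold from the freeze-index lineage; recorded in every report.
    threshold: float = 2.3
    min_sensors: int = 4

    def __post_init__(self) -> None:
        if self.threshold <= 0:
            raise ValueError("threshold must be positive")
        if not 1 <= self.min_sensors <= 7:
            raise ValueError("min_sensors must lie in [1, 7]")


@dataclass
class FreezeResult:
    step_times: np.ndarray
    fi_per_sensor: dict[str, np.ndarray]
    frozen_mask: np.ndarray
    percent_time_frozen: float
    threshold: float


def freeze_index_series(
    accel: np.ndarray, rate: float, config: FreezeConfig = FreezeConfig()
) -> tuple[np.ndarray, np.ndarray]:
    """Freeze index per sliding-window position for one sensor.

    Returns (step centre times, FI values).  FI is +inf where locomotor
    power is below machine tolerance.
    """
    accel = np.asarray(accel, dtype=float)
    magnitude = np.linalg.norm(accel, axis=1) if accel.ndim == 2 else accel
    n = len(magnitude)
    duration = n / rate
    if duration < config.window_s:
        warnings.warn(
            f"span {duration:.1f} s shorter than one {config.window_s} s FI window",
            stacklevel=2,
        )
        return np.empty(0), np.empty(0)

    half = config.window_s / 2.0
    centers = np.arange(0.0, duration + 1e-9, config.step_s)
    centers = centers[centers <= duration]
    fi = np.empty(len(centers))
    for k, c in enumerate(centers):
        i0 = max(0, int(round((c - half) * rate)))
        i1 = min(n, int(round((c + half) * rate)))
        win = sps.detrend(magnitude[i0:i1], type="linear")
        summary = psd(win, rate)
        p_freeze = summary.band_power(config.freeze_band)
        p_loco = summary.band_power(config.locomotor_band)
        if p_loco < _POWER_FLOOR or p_loco < _POWER_FLOOR * p_freeze:
            fi[k] = np.inf
        else:
            fi[k] = p_freeze / p_loco
    return centers, fi


def frozen_mask(
    fi_per_sensor: dict[str, np.ndarray], config: FreezeConfig = FreezeConfig()
) -> np.ndarray:
    """True where at least ``min_sensors`` of the sensors exceed the FI threshold."""
    series = list(fi_per_sensor.values())
    if len(series) != 7:
        raise ValueError(f"expected 7 gait-sensor FI series, got {len(series)}")
    lengths = {len(s) for s in series}
    if len(lengths) != 1:
        raise ValueError("FI series lengths differ across sensors")
    stacked = np.vstack(series)
    counts = np.sum(stacked > config.threshold, axis=0)
    return counts >= config.min_sensors


def percent_time_frozen(mask: np.ndarray) -> float:
    """100 × frozen steps / total steps; NaN for an empty mask."""
    mask = np.asarray(mask, dtype=bool)
    if mask.size == 0:
        return float("nan")
    return 100.0 * float(np.count_nonzero(mask)) / mask.size


def freeze_task(
    recording: Recording,
    annotation: TaskAnnotation,
    layout: SensorLayout,
    config: FreezeConfig = FreezeConfig(),
) -> FreezeResult:
    """Percent time frozen during one walking task."""
    seg = recording.slice(annotation.start_s, annotation.end_s)
    fi_per_sensor: dict[str, np.ndarray] = {}
    step_times = np.empty(0)
    for sensor in layout.fog_sensors:
        step_times, fi = freeze_index_series(seg.accel[sensor], seg.sampling_rate, config)
        fi_per_sensor[sensor] = fi
    if step_times.size == 0:
        return FreezeResult(step_times, fi_per_sensor, np.empty(0, dtype=bool),
                            float("nan"), config.threshold)
    mask = frozen_mask(fi_per_sensor, config)
    return FreezeResult(step_times, fi_per_sensor, mask,
                        percent_time_frozen(mask), config.threshold)
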