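"""Per-task quantification of choreic dyskinesia (LID).

Gyroscope axes of the non-task-involved sensors are band-pass filtered to
0.5–4 Hz; the per-frame Euclidean magnitude of each sensor forms a new time
series that is detrended, cut into 1 s windows and turned into a window
energy (total PSD power).  Sensor energies are averaged within each body
segment; per segment, window energies above the Q3 + 1.5·IQR threshold are
capped to the largest acceptable value (superfluous isolated voluntary
movements); the task score is the sum over segments of the mean (capped)
window energy — an average energy per second.

Sensor selection by posture: sitting tasks exclude the 6 arm sensors,
standing/walking tasks exclude the 6 leg sensors, leaving 11 sensors either
way.  Windows whose spectrum looks tremulous (dispersion < 2 Hz with a
dominant frequency at or above 3.5 Hz) are flagged, not silently dropped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import POSTURES, Recording, SensorLayout, TaskAnnotation
from .spectral import bandpass, dominant_and_dispersion, psd, window_slices


@dataclass(frozen=True)
class LidConfig:
    band: tuple[float, float] = (0.5, 4.0)
    window_s: float = 1.0
    outlier_q: float = 0.75
    outlier_k: float = 1.5
    cap_outliers: bool = True
    tremor_guard: bool = True
    guard_dispersion_hz: float = 2.0
    guard_min_fdom_hz: float = 3.5
    #: flagged tremor-confounded windows stay in the score unless True
    exclude_flagged: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.outlier_q < 1:
            raise ValueError("outlier_q must lie in (0, 1)")
        if self.outlier_k <= 0:
            raise ValueError("outlier_k must be positive")


@dataclass
class LidTaskScore:
    segments: list[str]
    #: raw (uncapped) window energies, shape (n_segments, n_windows)
    energies: np.ndarray
    pruned_count: int
    score: float
    flagged_tremor_windows: list[tuple[str, int]] = field(default_factory=list)


def lid_sensor_selection(layout: SensorLayout, posture: str) -> tuple[str, ...]:
    """Sensors entering the LID quantifier for a given task posture."""
    if posture not in POSTURES:
        raise ValueError(f"unknown posture {posture!r}")
    excluded = set(layout.arm_sensors if posture == "sitting" else layout.leg_sensors)
    return tuple(s for s in layout.placements if s not in excluded)


def magnitude_window_energies(
    magnitude: np.ndarray, rate: float, config: LidConfig = LidConfig()
) -> tuple[np.ndarray, list[int]]:
    """Window energies of one magnitude series plus tremor-guard flags.

    Returns (energies per 1 s window, indices of flagged windows).  The
    magnitude series is linearly detrended once (removing its positive
    offset and drift), then windowed; the energy of a window is the total
    power of its periodogram, i.e. the window variance.
    """
    magnitude = sps.detrend(np.asarray(magnitude, dtype=float), type="linear")
    slices = window_slices(len(magnitude), config.window_s, rate)
    energies = np.empty(len(slices))
    flagged: list[int] = []
    for k, sl in enumerate(slices):
        summary = psd(magnitude[sl], rate)
        energies[k] = summary.total_power
        if config.tremor_guard and summary.total_power > 0:
            d = dominant_and_dispersion(summary)
            if (
                d.dispersion_defined
                and d.dispersion_width < config.guard_dispersion_hz
                and d.f_dom is not None
                and d.f_dom >= config.guard_min_fdom_hz
            ):
                flagged.append(k)
    return energies, flagged


def segment_window_energies(
    recording: Recording,
    annotation: TaskAnnotation,
    layout: SensorLayout,
    config: LidConfig = LidConfig(),
) -> tuple[list[str], np.ndarray, list[tuple[str, int]]]:
    """Segment × window energy matrix for one task.

    Per selected sensor: band-pass each gyro axis, take the per-frame
    Euclidean magnitude, window and measure energies; segment energies are
    the mean over the segment's selected sensors.
    """
    seg_rec = recording.slice(annotation.start_s, annotation.end_s)
    if seg_rec.duration < config.window_s:
        warnings.warn(
            f"task {annotation.task_id}: span shorter than one {config.window_s} s window",
            stacklevel=2,
        )
        return [], np.empty((0, 0)), []

    sensors = lid_sensor_selection(layout, annotation.posture)
    rate = seg_rec.sampling_rate
    per_sensor: dict[str, np.ndarray] = {}
    sensor_flags: dict[str, list[int]] = {}
    for sensor in sensors:
        g = seg_rec.gyro[sensor]
        filt = np.column_stack([bandpass(g[:, ax], config.band, rate) for ax in range(3)])
        magnitude = np.linalg.norm(filt, axis=1)
        per_sensor[sensor], sensor_flags[sensor] = magnitude_window_energies(
            magnitude, rate, config
        )

    segments = [s for s, members in layout.segment_groups.items()
                if any(m in per_sensor for m in members)]
    n_windows = len(next(iter(per_sensor.values())))
    matrix = np.zeros((len(segments), n_windows))
    flagged: list[tuple[str, int]] = []
    for i, segment in enumerate(segments):
        members = [m for m in layout.segment_groups[segment] if m in per_sensor]
        matrix[i] = np.mean([per_sensor[m] for m in members], axis=0)
        seen = sorted({k for m in members for k in sensor_flags[m]})
        flagged += [(segment, k) for k in seen]
    return segments, matrix, flagged


def prune_energy_outliers(
    energies: np.ndarray, config: LidConfig = LidConfig()
) -> tuple[np.ndarray, int]:
    """Cap one segment's window energies at the Q3 + 1.5·IQR threshold.

    Quantiles use linear interpolation between order statistics.  Energies
    above the threshold are reset to the largest energy within it.  Fewer
    than 4 windows leave the energies untouched (quartiles undefined).
    """
    energies = np.asarray(energies, dtype=float)
    if len(energies) < 4:
        warnings.warn("fewer than 4 windows; outlier capping skipped", stacklevel=2)
        return energies.copy(), 0
    q1, q3 = np.quantile(energies, [1 - config.outlier_q, config.outlier_q])
    threshold = q3 + config.outlier_k * (q3 - q1)
    over = energies > threshold
    capped = energies.copy()
    if over.any():
        capped[over] = np.max(energies[~over])
    return capped, int(np.count_nonzero(over))


def lid_task_score(
    recording: Recording,
    annotation: TaskAnnotation,
    layout: SensorLayout,
    config: LidConfig = LidConfig(),
    override_windows: set[tuple[str, int]] | None = None,
) -> LidTaskScore:
    """Average LID energy per second for one task.

    ``override_windows`` lists (segment, window) pairs exempted from outlier
    capping, mirroring the manual video check of flagged outliers.
    """
    segments, matrix, flagged = segment_window_energies(recording, annotation, layout, config)
    if matrix.size == 0:
        return LidTaskScore(segments=[], energies=matrix, pruned_count=0, score=0.0)

    override_windows = override_windows or set()
    pruned_total = 0
    means = np.empty(len(segments))
    for i, segment in enumerate(segments):
        row = matrix[i]
        if config.cap_outliers:
            capped, n_pruned = prune_energy_outliers(row, config)
            exempt = [k for (seg, k) in override_windows if seg == segment]
            if exempt:
                restored = np.array(exempt, dtype=int)
                n_pruned -= int(np.count_nonzero(capped[restored] != row[restored]))
                capped[restored] = row[restored]
            pruned_total += n_pruned
            row = capped
        if config.exclude_flagged:
            drop = [k for (seg, k) in flagged if seg == segment]
            keep = np.setdiff1d(np.arange(len(row)), drop)
            row = row[keep] if len(keep) else row
        means[i] = float(np.mean(row))
    return LidTaskScore(
        segments=segments,
        energies=matrix,
        pruned_count=pruned_total,
        score=float(np.sum(means)),
        flagged_tremor_windows=flagged,
    )
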