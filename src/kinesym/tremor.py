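"""Per-task tremor quantification from hand gyroscopes.

All tremor types (rest, postural, kinetic) are treated alike: the hand
gyroscope axes are band-pass filtered to 3.5–7.5 Hz, detrended and cut into
5 s windows; per-axis PSDs are summed; a window is tremulous when the
68%-power dispersion around the dominant frequency is narrower than 2 Hz,
in which case its amplitude is the power inside the dispersion band.  Window
amplitudes are summed over windows and over both hands into the task level.

Wide-dispersion windows that nevertheless show a sharp peak (dominant bin
holding more than a quarter of total power) are flagged ``needs_review``
instead of being inspected visually; flagged windows can be exported as a
review log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .core import Recording, SensorLayout, TaskAnnotation
from .spectral import (
    DISPERSION_FRACTION,
    SpectralSummary,
    bandpass,
    dominant_and_dispersion,
    psd,
    window_slices,
)


@dataclass(frozen=True)
class TremorConfig:
    band: tuple[float, float] = (3.5, 7.5)
    window_s: float = 5.0
    dispersion_threshold_hz: float = 2.0
    review_peak_fraction: float = 0.25
    dispersion_fraction: float = DISPERSION_FRACTION
    dispersion_method: str = "minimal"
    #: how the two hands combine into one task level ("sum" or "max")
    hand_reduce: str = "sum"

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be positive")
        if self.dispersion_threshold_hz <= 0:
            raise ValueError("dispersion threshold must be positive")


@dataclass
class TremorWindowResult:
    window_index: int
    f_dom: float | None
    dispersion_width: float | None
    detected: bool
    amplitude: float  # summed in-dispersion-band power, (deg/s)^2
    needs_review: bool


@dataclass
class TremorTaskResult:
    level: float
    per_hand: dict[str, list[TremorWindowResult]]

    @property
    def review_rows(self) -> list[tuple[str, int, float, float]]:
        """(hand, window, f_dom, width) rows for the review log."""
        rows = []
        for hand, results in self.per_hand.items():
            for r in results:
                if r.needs_review:
                    rows.append((hand, r.window_index, r.f_dom, r.dispersion_width))
        return rows


def tremor_window(
    gyro_xyz: np.ndarray,
    rate: float,
    config: TremorConfig = TremorConfig(),
    window_index: int = 0,
) -> TremorWindowResult:
    """Score one already band-passed, detrended 3-axis window.

    Per-axis PSDs are summed into a total PSD before the dominant frequency
    and dispersion are computed, so a tremor oscillation split across axes
    is still seen as one narrow peak.
    """
    gyro_xyz = np.atleast_2d(np.asarray(gyro_xyz, dtype=float))
    if gyro_xyz.shape[1] != 3:
        gyro_xyz = gyro_xyz.T
    if not np.any(gyro_xyz):
        return TremorWindowResult(window_index, None, None, False, 0.0, False)

    summed = None
    for ax in range(3):
        s = psd(gyro_xyz[:, ax], rate)
        summed = s.psd if summed is None else summed + s.psd
    total = SpectralSummary(
        frequencies=s.frequencies, psd=summed, total_power=float(np.sum(summed) * s.df)
    )
    d = dominant_and_dispersion(
        total, fraction=config.dispersion_fraction, method=config.dispersion_method
    )
    detected = d.dispersion_defined and d.dispersion_width < config.dispersion_threshold_hz
    amplitude = d.dispersion_power if detected else 0.0
    needs_review = (
        not detected
        and d.dispersion_defined
        and float(np.max(summed)) * d.df > config.review_peak_fraction * d.total_power
    )
    return TremorWindowResult(
        window_index=window_index,
        f_dom=d.f_dom,
        dispersion_width=d.dispersion_width,
        detected=bool(detected),
        amplitude=float(amplitude),
        needs_review=bool(needs_review),
    )


def tremor_series(gyro: np.ndarray, rate: float, config: TremorConfig) -> list[TremorWindowResult]:
    """Band-pass, window and score one sensor's (n, 3) gyro series."""
    filtered = np.column_stack([bandpass(gyro[:, ax], config.band, rate) for ax in range(3)])
    slices = window_slices(len(filtered), config.window_s, rate)
    results = []
    for k, sl in enumerate(slices):
        win = sps.detrend(filtered[sl], axis=0, type="linear")
        results.append(tremor_window(win, rate, config, window_index=k))
    return results


def tremor_task(
    recording: Recording,
    annotation: TaskAnnotation,
    layout: SensorLayout,
    config: TremorConfig = TremorConfig(),
) -> TremorTaskResult:
    """Task tremor level: sum of detected window amplitudes over both hands."""
    seg = recording.slice(annotation.start_s, annotation.end_s)
    if seg.duration < config.window_s:
        warnings.warn(
            f"task {annotation.task_id}: span {seg.duration:.1f} s shorter than one "
            f"{config.window_s} s window; tremor level set to 0",
            stacklevel=2,
        )
        return TremorTaskResult(level=0.0, per_hand={h: [] for h in layout.hand_sensors})

    per_hand: dict[str, list[TremorWindowResult]] = {}
    hand_levels = []
    for hand in layout.hand_sensors:
        results = tremor_series(seg.gyro[hand], seg.sampling_rate, config)
        per_hand[hand] = results
        hand_levels.append(sum(r.amplitude for r in results))
    if config.hand_reduce == "sum":
        level = float(sum(hand_levels))
    elif config.hand_reduce == "max":
        level = float(max(hand_levels))
    else:
        raise ValueError(f"unknown hand_reduce {config.hand_reduce!r}")
    return TremorTaskResult(level=level, per_hand=per_hand)
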