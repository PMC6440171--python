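"""Reusable spectral primitives.

Filtering, detrending/windowing, periodogram PSD, dominant frequency and the
68%-power dispersion statistic shared by the tremor and dyskinesia stages.

Conventions (stated so results are reproducible bit-for-bit):

* Band-pass filter: 4th-order Butterworth applied forward-backward
  (zero phase, ``sosfiltfilt``).
* PSD: one-sided rectangular-window periodogram of the (constant-)detrended
  window, so the integral of the density over frequency equals the window
  variance (Parseval).
* Dispersion band: the minimal-width contiguous run of frequency bins that
  contains the dominant bin and holds at least the requested fraction of
  total power; ties prefer the lower-frequency band.  A greedy
  neighbour-annexation variant is available via ``method="greedy"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import signal as sps

FILTER_ORDER = 4
DISPERSION_FRACTION = 0.68


@dataclass(frozen=True)
class BandConfig:
    """Analysis frequency bands (Hz)."""

    tremor_band: tuple[float, float] = (3.5, 7.5)
    lid_band: tuple[float, float] = (0.5, 4.0)
    freeze_band: tuple[float, float] = (3.0, 8.0)
    locomotor_band: tuple[float, float] = (0.5, 3.0)

    def __post_init__(self) -> None:
        for name in ("tremor_band", "lid_band", "freeze_band", "locomotor_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name}: low edge must be below high edge")

    def validate_rate(self, rate: float) -> None:
        hi = max(b[1] for b in (
            self.tremor_band, self.lid_band, self.freeze_band, self.locomotor_band))
        if rate < 2.0 * hi:
            raise ValueError(f"sampling rate {rate} Hz below Nyquist need {2 * hi} Hz")


@dataclass
class SpectralSummary:
    """PSD plus dominant-frequency / power-dispersion statistics.

    ``psd`` is a one-sided density on the uniform ``frequencies`` grid;
    ``dispersion_band`` are bin-edge frequencies so that
    ``dispersion_width == hi - lo == n_bins * df``.
    """

    frequencies: np.ndarray
    psd: np.ndarray
    total_power: float
    f_dom: float | None = None
    dispersion_band: tuple[float, float] | None = None
    dispersion_width: float | None = None
    dispersion_fraction: float | None = None
    dispersion_power: float | None = None
    dispersion_defined: bool = True

    @property
    def df(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])

    def band_power(self, band: tuple[float, float]) -> float:
        """Power in ``[lo, hi)`` as the sum of in-band density bins × df."""
        lo, hi = band
        mask = (self.frequencies >= lo) & (self.frequencies < hi)
        return float(np.sum(self.psd[mask]) * self.df)


# ---------------------------------------------------------------------------
# Filtering and windowing
# ---------------------------------------------------------------------------

def _sos_bandpass(band: tuple[float, float], rate: float):
    lo, hi = band
    if rate <= 2.0 * hi:
        raise ValueError(f"sampling rate {rate} Hz too low for band edge {hi} Hz")
    return sps.butter(FILTER_ORDER, [lo, hi], btype="bandpass", fs=rate, output="sos")


def bandpass(x: np.ndarray, band: tuple[float, float], rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass; output has same length."""
    x = np.asarray(x, dtype=float)
    min_len = 3 * 2 * FILTER_ORDER  # forward-backward pad requirement
    if len(x) <= min_len:
        raise ValueError(f"signal too short to filter ({len(x)} <= {min_len} samples)")
    return sps.sosfiltfilt(_sos_bandpass(band, rate), x)


def lowpass(x: np.ndarray, cutoff: float, rate: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass."""
    x = np.asarray(x, dtype=float)
    if rate <= 2.0 * cutoff:
        raise ValueError(f"sampling rate {rate} Hz too low for cutoff {cutoff} Hz")
    sos = sps.butter(FILTER_ORDER, cutoff, btype="lowpass", fs=rate, output="sos")
    return sps.sosfiltfilt(sos, x)


def window_slices(n_samples: int, window_s: float, rate: float) -> list[slice]:
    """Index slices of consecutive non-overlapping windows; the trailing
    remainder shorter than one window is discarded."""
    n = int(round(window_s * rate))
    if n <= 0:
        raise ValueError("window_s must be positive")
    return [slice(i, i + n) for i in range(0, n_samples - n + 1, n)]


def detrend_and_window(x: np.ndarray, window_s: float, rate: float) -> list[np.ndarray]:
    """Split into non-overlapping windows with a per-window linear detrend."""
    x = np.asarray(x, dtype=float)
    slices = window_slices(len(x), window_s, rate)
    if not slices:
        warnings.warn(
            f"signal ({len(x)} samples) shorter than one {window_s} s window",
            stacklevel=2,
        )
        return []
    return [sps.detrend(x[s], type="linear") for s in slices]


# ---------------------------------------------------------------------------
# PSD
# ---------------------------------------------------------------------------

def psd(window: np.ndarray, rate: float) -> SpectralSummary:
    """One-sided rectangular-window periodogram of a single window.

    The integral of the returned density over frequency equals the window
    variance (Parseval), because the mean is removed before the transform.
    """
    window = np.asarray(window, dtype=float)
    if len(window) < 8:
        raise ValueError(f"window too short for PSD ({len(window)} < 8 samples)")
    if not np.all(np.isfinite(window)):
        raise ValueError("non-finite input to psd")
    freqs, pxx = sps.periodogram(window, fs=rate, window="boxcar", detrend="constant")
    df = freqs[1] - freqs[0]
    return SpectralSummary(frequencies=freqs, psd=pxx, total_power=float(np.sum(pxx) * df))


# ---------------------------------------------------------------------------
# Dominant frequency and power dispersion
# ---------------------------------------------------------------------------

def _minimal_band(p: np.ndarray, dom: int, target: float) -> tuple[int, int]:
    """Narrowest contiguous bin run containing ``dom`` with sum >= target.

    Ties prefer the lower-frequency run.  Linear scan over widths using a
    prefix sum; O(n^2) worst case, fine for periodogram-sized spectra.
    """
    csum = np.concatenate([[0.0], np.cumsum(p)])
    n = len(p)
    for width in range(1, n + 1):
        lo_start = max(0, dom - width + 1)
        hi_start = min(dom, n - width)
        for start in range(lo_start, hi_start + 1):
            if csum[start + width] - csum[start] >= target:
                return start, start + width - 1
    return 0, n - 1


def _greedy_band(p: np.ndarray, dom: int, target: float) -> tuple[int, int]:
    """Grow from the dominant bin, annexing the adjacent bin with greater
    power (ties annex the lower-frequency bin) until the target is met."""
    i0 = i1 = dom
    acc = p[dom]
    n = len(p)
    while acc < target and (i0 > 0 or i1 < n - 1):
        left = p[i0 - 1] if i0 > 0 else -np.inf
        right = p[i1 + 1] if i1 < n - 1 else -np.inf
        if left >= right:
            i0 -= 1
            acc += p[i0]
        else:
            i1 += 1
            acc += p[i1]
    return i0, i1


def dominant_and_dispersion(
    summary: SpectralSummary,
    fraction: float = DISPERSION_FRACTION,
    method: str = "minimal",
) -> SpectralSummary:
    """Complete a summary with dominant frequency and dispersion band.

    The dispersion band is the contiguous frequency band containing the
    dominant bin that holds at least ``fraction`` of total power; its width
    counts whole bins (a pure tone has width of one bin).  Zero total power
    yields an undefined-dispersion flag with the full band as width.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    df = summary.df
    freqs, p = summary.frequencies, summary.psd
    if summary.total_power <= 0 or not np.any(p > 0):
        band = (float(freqs[0]) - df / 2, float(freqs[-1]) + df / 2)
        return replace(
            summary,
            f_dom=None,
            dispersion_band=band,
            dispersion_width=band[1] - band[0],
            dispersion_fraction=fraction,
            dispersion_power=0.0,
            dispersion_defined=False,
        )
    dom = int(np.argmax(p))  # first maximum -> lower-frequency tie-break
    target = fraction * float(np.sum(p))
    if method == "minimal":
        i0, i1 = _minimal_band(p, dom, target)
    elif method == "greedy":
        i0, i1 = _greedy_band(p, dom, target)
    else:
        raise ValueError(f"unknown dispersion method {method!r}")
    band = (float(freqs[i0]) - df / 2, float(freqs[i1]) + df / 2)
    return replace(
        summary,
        f_dom=float(freqs[dom]),
        dispersion_band=band,
        dispersion_width=(i1 - i0 + 1) * df,
        dispersion_fraction=fraction,
        dispersion_power=float(np.sum(p[i0 : i1 + 1]) * df),
        dispersion_defined=True,
    )
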