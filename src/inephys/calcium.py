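"""ΔF/F normalization and spectral analysis of spontaneous calcium activity.

A fluorescence trace F(t) is normalized as ΔF/F = (F − F0)/F0 with F0
estimated (by default) as the mean of the lowest decile of the trace — a
baseline robust to transients.  Slow calcium oscillations are quantified
by a tapered periodogram: the power spectral density (PSD) is normalized
so that its integral over frequency equals the variance of the tapered,
mean-subtracted signal, and the band-limited peak (default band
0–0.1 Hz, upper edge inclusive) summarizes low-frequency oscillation
strength.  Event frequency counts prominent ΔF/F maxima per minute.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks, get_window

from .errors import ParameterError, ValidationError
from .io import TimeSeriesTrace

__all__ = [
    "DFFTrace",
    "SpectrumResult",
    "delta_f_over_f",
    "compute_spectrum",
    "event_frequency",
    "DEFAULT_BAND",
    "DEFAULT_PROMINENCE",
]

#: default low-frequency band of interest, (lo, hi] in Hz
DEFAULT_BAND = (0.0, 0.1)
#: default ΔF/F peak prominence for event counting
DEFAULT_PROMINENCE = 0.2


@dataclass
class DFFTrace:
    """Baseline-normalized fluorescence, (F − F0)/F0."""

    sampling_rate: float
    dff: np.ndarray
    f0: float

    def __post_init__(self):
        self.dff = np.asarray(self.dff, dtype=float)
        if not (self.f0 > 0):
            raise ValidationError(f"f0 must be > 0, got {self.f0}")
        if np.any(self.dff < -1.0 - 1e-12):
            raise ValidationError("dff below -1 implies negative fluorescence")

    @property
    def duration(self) -> float:
        return self.dff.size / self.sampling_rate


@dataclass
class SpectrumResult:
    """Periodogram of a ΔF/F trace with band-limited peak statistics."""

    freqs: np.ndarray
    power: np.ndarray
    psd: np.ndarray
    band: tuple[float, float]
    band_peak_psd: float
    band_peak_freq: float

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def delta_f_over_f(trace: TimeSeriesTrace, f0_method: str = "lowest_decile") -> DFFTrace:
    """Normalize a fluorescence trace to ΔF/F.

    ``f0_method``: ``"lowest_decile"`` (mean of the lowest 10% of samples,
    default), ``"mean"``, ``"median"``, or ``"percentile:<q>"``.
    """
    if trace.unit != "AFU":
        raise ValidationError(f"ΔF/F needs a fluorescence trace, got unit {trace.unit!r}")
    f = trace.values
    if np.any(f < 0):
        raise ValidationError("fluorescence values must be non-negative")
    if f0_method == "lowest_decile":
        k = max(1, f.size // 10)
        f0 = float(np.mean(np.sort(f)[:k]))
    elif f0_method == "mean":
        f0 = float(np.mean(f))
    elif f0_method == "median":
        f0 = float(np.median(f))
    elif f0_method.startswith("percentile:"):
        q = float(f0_method.split(":", 1)[1])
        f0 = float(np.percentile(f, q))
    else:
        raise ParameterError(f"unknown f0_method {f0_method!r}")
    if f0 <= 0:
        raise ValidationError(f"estimated F0 = {f0:g} is not positive")
    return DFFTrace(sampling_rate=trace.sampling_rate, dff=(f - f0) / f0, f0=f0)


def compute_spectrum(
    dff: DFFTrace,
    band: tuple[float, float] = DEFAULT_BAND,
    window: str = "hann",
    detrend: str = "linear",
) -> SpectrumResult:
    """Tapered periodogram of a ΔF/F trace.

    The signal is mean-subtracted (and, by default, linearly detrended so
    slow drift does not masquerade as 0–0.02 Hz power), multiplied by the
    taper ``window``, and Fourier-transformed.  ``psd`` is normalized so
    that sum(psd)·Δf equals the variance of the tapered signal (tapered
    sum of squares divided by the window power); ``power`` is the
    one-sided power spectrum (amplitude-squared per bin).  The band is
    (lo, hi] — the lower edge is exclusive, which drops the DC bin for
    the default 0–0.1 Hz band.
    """
    x = np.asarray(dff.dff, dtype=float)
    if x.size < 64:
        raise ValidationError(f"spectrum needs >= 64 samples, got {x.size}")
    fs = dff.sampling_rate
    nyq = fs / 2.0
    lo, hi = band
    if hi > nyq + 1e-12 or lo < 0 or hi <= lo:
        raise ParameterError(f"band {band} is not within (0, Nyquist={nyq:g}] Hz")

    if detrend == "linear":
        t = np.arange(x.size)
        x = x - np.polyval(np.polyfit(t, x, 1), t)
    elif detrend in (None, "none"):
        pass
    else:
        raise ParameterError(f"unknown detrend {detrend!r}")
    x = x - np.mean(x)

    w = get_window(window, x.size)
    xw = x * w
    n = x.size
    spec = np.fft.rfft(xw)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    mag2 = np.abs(spec) ** 2
    # one-sided doubling keeps Parseval exact
    scale = np.ones_like(mag2)
    scale[1:] = 2.0
    if n % 2 == 0:
        scale[-1] = 1.0
    psd = mag2 * scale / (fs * np.sum(w**2))
    power = mag2 * scale / (np.sum(w) ** 2)

    mask = (freqs > lo) & (freqs <= hi + 1e-12)
    if not np.any(mask):
        raise ParameterError(f"band {band} contains no frequency bins (Δf = {fs / n:g} Hz)")
    j = int(np.argmax(psd[mask]))
    band_freqs = freqs[mask]
    return SpectrumResult(
        freqs=freqs,
        power=power,
        psd=psd,
        band=(lo, hi),
        band_peak_psd=float(psd[mask][j]),
        band_peak_freq=float(band_freqs[j]),
    )


def event_frequency(dff: DFFTrace, prominence: float = DEFAULT_PROMINENCE) -> float:
    """Calcium events per minute: local ΔF/F maxima with at least the given
    prominence."""
    if not (prominence > 0):
        raise ParameterError(f"prominence must be > 0, got {prominence}")
    peaks, _ = find_peaks(dff.dff, prominence=prominence)
    minutes = dff.duration / 60.0
    return float(peaks.size / minutes)
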