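"""Welch power spectra, Morlet wavelet spectrograms, background segments.

Spectra follow the study conventions of absence-seizure EEG work: Hann-
windowed averaged periodograms with a fixed 2 s window and 7/8 overlap,
giving a 0.5 Hz frequency resolution; discharge spectra are averaged over
many events, and discharge time-frequency dynamics are examined with a
complex Morlet wavelet transform.
"""

from __future__ import annotations

import numpy as np
import pywt
from scipy import signal as sps

from .types import ParameterError, PowerSpectrum, Spectrogram, SWDEvent, EEGRecording

__all__ = [
    "welch_psd",
    "average_spectra",
    "morlet_spectrogram",
    "extract_background_segments",
]

DEFAULT_FMAX = 25.0  # Hz; the analysis band of rodent SWD spectra


def welch_psd(
    x: np.ndarray,
    sampling_rate: float,
    window_length: float = 2.0,
    overlap_fraction: float = 7.0 / 8.0,
    fmax: float | None = DEFAULT_FMAX,
) -> PowerSpectrum:
    """One-sided Welch PSD (µV²/Hz) with Hann windows.

    Bin spacing is exactly ``1/window_length`` (0.5 Hz for the 2 s default).
    Each window is mean-detrended before tapering so DC does not leak into
    the lowest bins.  Segments shorter than one window raise an error — no
    silent zero-padding.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ParameterError("welch_psd expects a 1-D signal")
    nperseg = int(round(window_length * sampling_rate))
    if not 0 <= overlap_fraction < 1:
        raise ParameterError("overlap_fraction must lie in [0, 1)")
    if nperseg < 2:
        raise ParameterError("window_length too short for this sampling rate")
    if x.size < nperseg:
        raise ParameterError(
            f"segment of {x.size / sampling_rate:.3f} s shorter than the "
            f"{window_length} s analysis window"
        )
    noverlap = int(round(nperseg * overlap_fraction))
    freqs, power = sps.welch(
        x,
        fs=sampling_rate,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        return_onesided=True,
    )
    step = nperseg - noverlap
    n_segments = 1 + (x.size - nperseg) // step
    if fmax is not None:
        keep = freqs <= fmax + 1e-9
        freqs, power = freqs[keep], power[keep]
    return PowerSpectrum(frequencies=freqs, power=power, n_segments=int(n_segments))


def average_spectra(spectra: list[PowerSpectrum]) -> PowerSpectrum:
    """Pointwise arithmetic mean of spectra on a common frequency grid."""
    if not spectra:
        raise ParameterError("no spectra to average")
    grid = spectra[0].frequencies
    for s in spectra[1:]:
        if s.frequencies.shape != grid.shape or not np.allclose(s.frequencies, grid):
            raise ParameterError("spectra are on different frequency grids")
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(
        frequencies=grid.copy(),
        power=power,
        n_segments=int(sum(s.n_segments for s in spectra)),
    )


def morlet_spectrogram(
    x: np.ndarray,
    sampling_rate: float,
    freq_range: tuple[float, float] = (1.0, 25.0),
    freq_step: float = 0.25,
    bandwidth: float = 1.5,
    center_frequency: float = 1.0,
) -> Spectrogram:
    """Magnitude of the complex Morlet wavelet transform on a frequency grid.

    ``bandwidth``/``center_frequency`` parameterize the ``cmorB-C`` wavelet;
    the defaults give roughly six oscillations under the Gaussian envelope at
    each analysis frequency — the usual trade-off for 5-25 Hz EEG rhythms.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = freq_range
    if not 0 < lo < hi:
        raise ParameterError("freq_range must satisfy 0 < lo < hi")
    if hi > sampling_rate / 2:
        raise ParameterError("freq_range exceeds the Nyquist frequency")
    freqs = np.arange(lo, hi + freq_step / 2, freq_step)
    wavelet = f"cmor{bandwidth}-{center_frequency}"
    scales = center_frequency * sampling_rate / freqs
    coefs, _ = pywt.cwt(x, scales, wavelet, sampling_period=1.0 / sampling_rate)
    times = np.arange(x.size) / sampling_rate
    return Spectrogram(
        times=times,
        frequencies=freqs,
        magnitude=np.abs(coefs),
        wavelet_params={"bandwidth": bandwidth, "center_frequency": center_frequency},
    )


def _segment_free_interval(length: float, min_len: float = 8.0,
                           max_len: float = 10.0) -> list[float]:
    """Segment sizes maximizing coverage of one free interval.

    Prefers the fewest segments that still cover the whole interval with
    sizes in [min_len, max_len]; when full coverage is impossible, packs
    max_len segments.
    """
    if length < min_len:
        return []
    n = int(np.ceil(length / max_len))
    if length / n >= min_len:
        return [length / n] * n
    n = int(length // min_len)
    return [max_len] * n


def extract_background_segments(
    recording: EEGRecording,
    events: list[SWDEvent],
    margin: float = 2.0,
    min_len: float = 8.0,
    max_len: float = 10.0,
) -> list[tuple[float, float]]:
    """Non-overlapping 8-10 s quiet-wakefulness intervals away from discharges.

    Returns ``(start, stop)`` pairs in seconds, each at least ``margin``
    (default 2 s) from every event boundary, packed for maximal coverage.
    May be empty when no stretch of at least ``min_len`` seconds remains.
    """
    total = recording.duration
    forbidden = [(max(e.onset - margin, 0.0), min(e.offset + margin, total))
                 for e in sorted(events, key=lambda e: e.onset)]
    free: list[tuple[float, float]] = []
    cursor = 0.0
    for lo, hi in forbidden:
        if lo > cursor:
            free.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < total:
        free.append((cursor, total))

    out: list[tuple[float, float]] = []
    for lo, hi in free:
        t = lo
        for size in _segment_free_interval(hi - lo, min_len, max_len):
            out.append((t, t + size))
            t += size
    return out
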