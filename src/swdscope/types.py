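"""Shared domain containers for EEG recordings, discharge events and results.

Conventions used throughout the package:

* signals are in microvolts (µV), time in seconds from recording start;
* event intervals are half-open ``[onset, offset)``;
* arrays are NumPy, recordings are ``(n_channels, n_samples)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "ParameterError",
    "PackingError",
    "DegenerateSignalError",
    "EEGRecording",
    "SWDEvent",
    "SWDAnnotation",
    "SessionSummary",
    "MorphologyMetrics",
    "PowerSpectrum",
    "Spectrogram",
    "StatResult",
    "SpectralComparison",
]


class ParameterError(ValueError):
    """An invalid parameter or configuration value."""


class PackingError(RuntimeError):
    """Requested events cannot be placed in the session without violating gaps."""


class DegenerateSignalError(ValueError):
    """A computation received a signal it cannot meaningfully analyse."""


@dataclass(frozen=True)
class EEGRecording:
    """Uniformly sampled multi-channel EEG in µV.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``.
    sampling_rate
        Sampling rate in Hz.
    channel_labels
        One label per channel (e.g. ``("frontal", "occipital")``).
    """

    samples: np.ndarray
    sampling_rate: float
    channel_labels: tuple[str, ...] = ("frontal",)

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim == 1:
            arr = arr[np.newaxis, :]
        if arr.ndim != 2 or arr.shape[0] < 1:
            raise ParameterError("samples must be a 1-D or (n_channels, n_samples) array")
        if not np.all(np.isfinite(arr)):
            raise ParameterError("EEG samples must be finite")
        if not self.sampling_rate > 0:
            raise ParameterError("sampling_rate must be positive")
        if len(self.channel_labels) != arr.shape[0]:
            raise ParameterError(
                f"{len(self.channel_labels)} labels for {arr.shape[0]} channels"
            )
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sampling_rate

    def channel(self, label: str | None = None) -> np.ndarray:
        """Return one channel's trace; default is the first channel."""
        if label is None:
            return self.samples[0]
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise ParameterError(
                f"unknown channel {label!r}; have {self.channel_labels}"
            ) from None
        return self.samples[idx]

    def slice_seconds(self, start: float, stop: float, label: str | None = None) -> np.ndarray:
        """Samples of the half-open interval ``[start, stop)`` seconds."""
        i0 = int(np.ceil(start * self.sampling_rate - 1e-9))
        i1 = int(np.ceil(stop * self.sampling_rate - 1e-9))
        return self.channel(label)[max(i0, 0) : max(i1, 0)]


@dataclass(frozen=True)
class SWDEvent:
    """One detected spike-wave discharge, half-open ``[onset, offset)`` seconds."""

    onset: float
    offset: float
    channel: str = "frontal"

    def __post_init__(self) -> None:
        if not self.offset > self.onset:
            raise ParameterError("event offset must exceed onset")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass(frozen=True)
class SWDAnnotation:
    """Ground-truth record of one injected discharge."""

    onset: float
    offset: float
    variant: str
    true_amplitude: float
    true_asymmetry: float
    true_frequency_track: tuple[float, ...] = field(default_factory=tuple)

    @property
    def duration(self) -> float:
        return self.offset - self.onset

    def as_event(self, channel: str = "frontal") -> SWDEvent:
        return SWDEvent(self.onset, self.offset, channel)


@dataclass(frozen=True)
class SessionSummary:
    """Seizure burden of one session: count, total and mean discharge duration.

    The mean is the ratio of total duration to the number of discharges and is
    absent (``None``) for an empty session.
    """

    n_events: int
    total_duration: float
    mean_duration: float | None


@dataclass(frozen=True)
class MorphologyMetrics:
    """Per-discharge morphology: spikes, mean amplitude, asymmetry, maturity."""

    spike_times: tuple[float, ...]
    spike_amplitudes: tuple[float, ...]
    mean_amplitude: float | None
    asymmetry_index: float
    maturity: str


@dataclass(frozen=True)
class PowerSpectrum:
    """One-sided Welch power spectral density in µV²/Hz on a uniform grid."""

    frequencies: np.ndarray
    power: np.ndarray
    n_segments: int = 1

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies, dtype=float)
        p = np.asarray(self.power, dtype=float)
        if f.shape != p.shape or f.ndim != 1:
            raise ParameterError("frequencies and power must be equal-length 1-D arrays")
        if np.any(p < 0):
            raise ParameterError("power must be non-negative")
        object.__setattr__(self, "frequencies", f)
        object.__setattr__(self, "power", p)

    @property
    def df(self) -> float:
        """Frequency bin spacing in Hz."""
        return float(self.frequencies[1] - self.frequencies[0])


@dataclass(frozen=True)
class Spectrogram:
    """Magnitude of a complex Morlet wavelet transform."""

    times: np.ndarray
    frequencies: np.ndarray
    magnitude: np.ndarray
    wavelet_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        m = np.asarray(self.magnitude, dtype=float)
        if m.shape != (len(self.frequencies), len(self.times)):
            raise ParameterError("magnitude must be (n_frequencies, n_times)")
        if np.any(m < 0):
            raise ParameterError("magnitude must be non-negative")
        object.__setattr__(self, "magnitude", m)

    def ridge(self) -> np.ndarray:
        """Per-time-point frequency of maximal magnitude (diagnostic ridge)."""
        return np.asarray(self.frequencies)[np.argmax(self.magnitude, axis=0)]


@dataclass(frozen=True)
class StatResult:
    """Outcome of one hypothesis test, with Bonferroni-adjusted p-value."""

    test: str
    statistic: float
    df: tuple[int, ...] | None
    p_raw: float
    multiplicity_factor: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_raw <= 1.0):
            raise ParameterError("p_raw must lie in [0, 1]")
        if self.multiplicity_factor < 1:
            raise ParameterError("multiplicity_factor must be a positive integer")

    @property
    def p_adjusted(self) -> float:
        return min(1.0, self.multiplicity_factor * self.p_raw)


@dataclass(frozen=True)
class SpectralComparison:
    """Frequency-wise two-group comparison of power spectra."""

    frequencies: np.ndarray
    results: tuple[StatResult, ...]
    n_frequencies: int
    n_comparisons: int
    alpha: float

    @property
    def multiplicity_factor(self) -> int:
        return self.n_frequencies * self.n_comparisons

    @property
    def flagged(self) -> np.ndarray:
        """Boolean mask of bins significant after Bonferroni adjustment."""
        return np.array([r.p_adjusted < self.alpha for r in self.results])


def events_sorted_nonoverlapping(events: Sequence[SWDEvent]) -> bool:
    """True when events are in time order and pairwise disjoint."""
    for a, b in zip(events, events[1:]):
        if b.onset < a.offset:
            return False
    return True
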