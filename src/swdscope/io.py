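"""File formats: EDF recordings, delimited signal matrices, event tables.

Recordings round-trip through EDF (16-bit, physical units µV) or through a
plain CSV matrix whose first line is a ``# key=value`` header carrying the
sampling rate.  EDF files are written by a small built-in writer (one data
record per second, symmetric digital range so physical values decode as
``digital * physical_max / 32767``) and read back with MNE.

All event tables are CSV with seconds serialized at 3-decimal precision and
the half-open ``[onset, offset)`` convention stated in a comment header.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EEGRecording, MorphologyMetrics, ParameterError, SWDAnnotation, SWDEvent

__all__ = [
    "write_edf",
    "write_matrix",
    "read_recording",
    "write_events",
    "read_events",
    "write_ground_truth",
    "read_ground_truth",
]

_RATE_KEY = "sampling_rate_hz"


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as 16-bit EDF with physical units in µV.

    Uses 1 s data records (the last record is zero-padded) and a symmetric
    digital range of ±32767, so quantization error is at most
    ``physical_max / 32767`` µV.  Requires an integer sampling rate.
    """
    path = Path(path)
    fs = recording.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ParameterError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n = recording.n_samples
    n_records = int(np.ceil(n / spr))
    ns = recording.n_channels
    phys_max = int(np.ceil(max(float(np.max(np.abs(recording.samples))), 1.0)))

    with open(path, "wb") as fh:
        fh.write(_pad("0", 8))
        fh.write(_pad("X X X X", 80))
        fh.write(_pad("Startdate 01-JAN-2001 X X X", 80))
        fh.write(_pad("01.01.01", 8))
        fh.write(_pad("00.00.00", 8))
        fh.write(_pad(str(256 * (ns + 1)), 8))
        fh.write(_pad("", 44))
        fh.write(_pad(str(n_records), 8))
        fh.write(_pad("1", 8))
        fh.write(_pad(str(ns), 4))
        for label in recording.channel_labels:
            fh.write(_pad(label, 16))
        fh.write(_pad("", 80) * ns)
        fh.write(_pad("uV", 8) * ns)
        fh.write(_pad(str(-phys_max), 8) * ns)
        fh.write(_pad(str(phys_max), 8) * ns)
        fh.write(_pad("-32767", 8) * ns)
        fh.write(_pad("32767", 8) * ns)
        fh.write(_pad("", 80) * ns)
        fh.write(_pad(str(spr), 8) * ns)
        fh.write(_pad("", 32) * ns)

        scale = 32767.0 / phys_max
        padded = np.zeros((ns, n_records * spr))
        padded[:, :n] = recording.samples
        digital = np.clip(np.round(padded * scale), -32767, 32767).astype("<i2")
        for r in range(n_records):
            for ch in range(ns):
                fh.write(digital[ch, r * spr : (r + 1) * spr].tobytes())
    return path


def write_matrix(recording: EEGRecording, path: str | Path) -> Path:
    """Write a recording as a CSV matrix with a sampling-rate header line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {_RATE_KEY}={recording.sampling_rate:g}\n")
        fh.write(",".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.samples.T, delimiter=",", fmt="%.6f")
    return path


def _read_matrix(path: Path) -> EEGRecording:
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("#") or "=" not in first:
            raise ParameterError(
                f"{path} has no '# {_RATE_KEY}=<Hz>' header line; sampling rate unknown"
            )
        key, _, value = first.lstrip("# ").partition("=")
        if key.strip() != _RATE_KEY:
            raise ParameterError(f"missing required header field {_RATE_KEY!r}")
        rate = float(value)
        frame = pd.read_csv(fh)
    if frame.empty:
        raise ParameterError(f"{path} contains no samples")
    data = frame.to_numpy(dtype=float).T
    return EEGRecording(data, rate, tuple(str(c) for c in frame.columns))


def _read_edf(path: Path) -> EEGRecording:
    import mne  # deferred: mne import is slow

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e6  # MNE loads EEG in volts
    return EEGRecording(data, float(raw.info["sfreq"]), tuple(raw.ch_names))


def read_recording(path: str | Path, channel: str | None = None) -> EEGRecording:
    """Read an EDF or header-carrying CSV matrix recording (µV).

    With ``channel`` given, returns a single-channel recording of that trace.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    suffix = path.suffix.lower()
    if suffix == ".edf":
        rec = _read_edf(path)
    elif suffix in (".csv", ".txt", ".tsv"):
        rec = _read_matrix(path)
    else:
        raise ParameterError(f"unknown recording format {suffix!r} (expect .edf or .csv)")
    if channel is not None:
        rec = EEGRecording(rec.channel(channel)[np.newaxis, :], rec.sampling_rate, (channel,))
    return rec


_EVENT_COLUMNS = [
    "onset_s", "offset_s", "duration_s",
    "mean_amplitude_uV", "asymmetry_pct", "maturity",
]


def events_to_frame(
    events: list[SWDEvent],
    metrics: list[MorphologyMetrics] | None = None,
) -> pd.DataFrame:
    """Tidy per-event table; morphology columns are NaN/empty when absent."""
    rows = []
    for i, ev in enumerate(events):
        m = metrics[i] if metrics else None
        rows.append({
            "onset_s": round(ev.onset, 3),
            "offset_s": round(ev.offset, 3),
            "duration_s": round(ev.duration, 3),
            "mean_amplitude_uV": (
                round(m.mean_amplitude, 3) if m and m.mean_amplitude is not None else np.nan
            ),
            "asymmetry_pct": round(m.asymmetry_index, 3) if m else np.nan,
            "maturity": m.maturity if m else "",
        })
    return pd.DataFrame(rows, columns=_EVENT_COLUMNS)


def write_events(
    events: list[SWDEvent],
    path: str | Path,
    metrics: list[MorphologyMetrics] | None = None,
    config_hash: str = "",
) -> Path:
    """Write the event/metrics table as CSV (header line + one row per event)."""
    path = Path(path)
    frame = events_to_frame(events, metrics)
    with open(path, "w") as fh:
        fh.write(f"# intervals in seconds, half-open [onset, offset); "
                 f"config_hash={config_hash}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_events(path: str | Path, channel: str = "frontal") -> tuple[list[SWDEvent], pd.DataFrame]:
    """Read an event CSV back into events plus the full metrics frame."""
    frame = pd.read_csv(path, comment="#")
    events = [SWDEvent(float(r.onset_s), float(r.offset_s), channel)
              for r in frame.itertuples()]
    return events, frame


def write_ground_truth(
    annotations: list[SWDAnnotation], path: str | Path, config_hash: str = ""
) -> Path:
    """Ground-truth annotation CSV emitted next to a simulated recording."""
    path = Path(path)
    rows = [{
        "onset_s": round(a.onset, 3),
        "offset_s": round(a.offset, 3),
        "variant": a.variant,
        "amplitude_uV": round(a.true_amplitude, 3),
        "asymmetry": round(a.true_asymmetry / 100.0, 4),
        "steady_hz": round(a.true_frequency_track[-1], 3) if a.true_frequency_track else np.nan,
    } for a in annotations]
    frame = pd.DataFrame(
        rows, columns=["onset_s", "offset_s", "variant", "amplitude_uV",
                       "asymmetry", "steady_hz"])
    with open(path, "w") as fh:
        fh.write(f"# intervals in seconds, half-open [onset, offset); "
                 f"config_hash={config_hash}\n")
        frame.to_csv(fh, index=False, lineterminator="\n")
    return path


def read_ground_truth(path: str | Path) -> list[SWDAnnotation]:
    frame = pd.read_csv(path, comment="#")
    return [
        SWDAnnotation(
            onset=float(r.onset_s), offset=float(r.offset_s), variant=str(r.variant),
            true_amplitude=float(r.amplitude_uV),
            true_asymmetry=100.0 * float(r.asymmetry),
            true_frequency_track=(float(r.steady_hz),) if np.isfinite(r.steady_hz) else (),
        )
        for r in frame.itertuples()
    ]


def write_json(obj, path: str | Path) -> Path:
    """Deterministic JSON (sorted keys, fixed separators)."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def spectrum_to_frame(freqs: np.ndarray, power: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({"frequency_hz": np.round(freqs, 4), "power_uV2_per_hz": power})


def write_spectrum(freqs, power, path: str | Path, config_hash: str = "") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# one-sided Welch PSD; config_hash={config_hash}\n")
        spectrum_to_frame(freqs, power).to_csv(
            fh, index=False, lineterminator="\n", float_format="%.8g")
    return path
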