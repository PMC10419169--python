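"""Synthetic rodent cortical EEG with annotated spike-wave discharges (SWDs).

Emulates the phenomenology of absence-epilepsy EEG: a low-amplitude colored
background interrupted by rhythmic ~7-8 Hz trains of sharp, asymmetric,
large-amplitude spikes alternating with slow waves.  Every injected event is
reported with its true onset/offset, variant, amplitude, asymmetry and
per-cycle frequency track, so detection, morphology and spectral estimators
can be validated by parameter recovery instead of expert annotation.

Waveform model (phenomenological, not biophysical).  Each spike-wave cycle of
period ``T`` is a piecewise sum of shaped pulses laid out over the cycle:

* an early positive transient (small Gaussian bump),
* a sharp negative spike (narrow Gaussian, peak = the configured amplitude),
* a late positive transient,
* a slow biphasic wave: a negative half-sine lobe followed by a positive
  rebound half-sine.

The rebound amplitude is calibrated numerically (per discharge) so that the
asymmetry index measured by :func:`swdscope.morphology.asymmetry_of_samples`
on the clean segment equals the requested negative-area share.  The cycle
rate settles linearly from ``fundamental_start_hz`` to ``fundamental_steady_hz``
over the first second, reproducing the decreasing time-frequency ridge of
real discharges.

Variants:

``mature``
    a spike and a wave in every cycle;
``immature``
    spikes dropped in a random 40% of cycles, waves present in a random half
    of the cycles only (operationalizing "fewer sharp spikes and irregular
    presence of a wave"; the fractions are package conventions);
``fused``
    several mature sub-trains separated by 0.3 s pauses, merged into one long
    event (these can reach ~100 s);
``atypical``
    a high-amplitude (~3000 µV) three-part discharge: a spikes-only onset,
    a 2-3 Hz middle of inverted polarity, and a <1 Hz terminal part.

Inside an event interval the discharge waveform replaces the background: a
discharge dominates the trace, and replacement keeps the ground truth of
every morphology parameter exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.signal import lfilter

from .morphology import asymmetry_of_samples
from .types import EEGRecording, PackingError, ParameterError, SWDAnnotation

__all__ = [
    "GeneratorConfig",
    "CycleInfo",
    "DischargeSegment",
    "generate_background",
    "synthesize_discharge",
    "generate_session",
    "VARIANTS",
]

VARIANTS = ("mature", "immature", "fused", "atypical")

# Cycle layout in fractions of the period; the spike width is fixed in
# seconds so spikes stay sharp even in slow (atypical) cycles.
_PT_EARLY_CENTER, _PT_EARLY_SIGMA, _PT_EARLY_AMP = 0.06, 0.02, 0.08
_SPIKE_CENTER, _SPIKE_SIGMA_S = 0.14, 0.006
_PT_LATE_CENTER, _PT_LATE_SIGMA, _PT_LATE_AMP = 0.22, 0.02, 0.07
_WAVE_NEG_START, _WAVE_NEG_WIDTH, _WAVE_NEG_AMP = 0.30, 0.32, 0.40
_REBOUND_START, _REBOUND_WIDTH = 0.66, 0.28

_IMMATURE_SPIKE_DROP = 0.40   # fraction of cycles without a sharp spike
_IMMATURE_WAVE_KEEP = 0.50    # fraction of cycles retaining a wave
_FUSED_GAP = 0.3              # s of silence between fused sub-trains
_FUSED_CHUNK = (3.0, 6.0)     # s, sub-train length range
_AR_COEFF = 0.95              # AR(1) pole of the background noise


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of one simulated EEG session.

    Defaults mirror typical recording conditions of a 7-month-old WAG/Rij
    rat: 7-8 Hz discharges of a few seconds, spike peaks near 900 µV over a
    ~50 µV RMS background, and a ~69% negative-area share.
    """

    sampling_rate: float = 400.0
    session_length: float = 300.0
    background_rms: float = 50.0
    swd_count: int = 10
    swd_duration_range: tuple[float, float] = (2.0, 8.0)
    swd_amplitude: float = 900.0
    asymmetry: float = 0.69
    fundamental_start_hz: float = 9.5
    fundamental_steady_hz: float = 7.5
    variant_mix: dict[str, float] = field(default_factory=lambda: {"mature": 1.0})
    min_gap: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0 or self.session_length <= 0:
            raise ParameterError("sampling_rate and session_length must be positive")
        highest = 3.0 * max(self.fundamental_start_hz, self.fundamental_steady_hz)
        if self.sampling_rate < 4.0 * highest:
            raise ParameterError(
                f"sampling_rate {self.sampling_rate} Hz < 4x highest synthesized "
                f"frequency ({highest} Hz)"
            )
        lo, hi = self.swd_duration_range
        if not (1.0 <= lo <= hi <= 120.0):
            raise ParameterError("swd_duration_range must lie within [1, 120] s")
        if not (0.0 < self.asymmetry < 1.0):
            raise ParameterError("asymmetry must lie in (0, 1)")
        if self.background_rms < 0:
            raise ParameterError("background_rms must be non-negative")
        if self.swd_count < 0:
            raise ParameterError("swd_count must be non-negative")
        if self.min_gap < 0:
            raise ParameterError("min_gap must be non-negative")
        unknown = set(self.variant_mix) - set(VARIANTS)
        if unknown:
            raise ParameterError(f"unknown variants in mix: {sorted(unknown)}")
        if self.variant_mix and not np.isclose(sum(self.variant_mix.values()), 1.0):
            raise ParameterError("variant_mix proportions must sum to 1")
        needed = self.swd_count * hi + (self.swd_count + 1) * self.min_gap
        if self.swd_count and needed > self.session_length:
            raise ParameterError(
                f"{self.swd_count} events of up to {hi} s plus {self.min_gap} s gaps "
                f"do not fit in {self.session_length} s"
            )


@dataclass(frozen=True)
class CycleInfo:
    """One annotated spike-wave cycle of a synthesized discharge."""

    start: float
    period: float
    frequency: float
    has_spike: bool = True
    has_wave: bool = True
    inverted: bool = False


@dataclass(frozen=True)
class DischargeSegment:
    """Clean (noise-free) discharge waveform plus its per-cycle annotation."""

    samples: np.ndarray
    sampling_rate: float
    cycles: tuple[CycleInfo, ...]
    variant: str
    amplitude: float
    asymmetry_measured: float

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate


def generate_background(config: GeneratorConfig, length: float,
                        rng: np.random.Generator | None = None) -> EEGRecording:
    """Zero-mean colored background noise scaled to ``background_rms``.

    First-order autoregressive noise (pole 0.95), whose spectrum falls with
    frequency like resting EEG.  Deterministic given ``config.seed`` (unless
    an explicit ``rng`` is supplied).
    """
    if length <= 0:
        raise ParameterError("length must be positive")
    if config.background_rms < 0:
        raise ParameterError("background_rms must be non-negative")
    n = int(round(length * config.sampling_rate))
    if config.background_rms == 0.0:
        return EEGRecording(np.zeros((1, n)), config.sampling_rate)
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    white = rng.standard_normal(n + 400)
    colored = lfilter([1.0], [1.0, -_AR_COEFF], white)[400:]  # drop filter warm-up
    colored -= colored.mean()
    colored *= config.background_rms / np.sqrt(np.mean(colored**2))
    return EEGRecording(colored[np.newaxis, :], config.sampling_rate)


def _cycle_schedule(duration: float, freq_track, start_hz: float,
                    steady_hz: float) -> list[tuple[float, float]]:
    """Sequential (start, period) pairs filling ``duration`` with whole cycles."""
    cycles: list[tuple[float, float]] = []
    t = 0.0
    k = 0
    while True:
        if freq_track is None:
            f = start_hz + (steady_hz - start_hz) * min(t, 1.0)
        elif np.isscalar(freq_track):
            f = float(freq_track)
        else:
            track = np.asarray(freq_track, dtype=float)
            f = float(track[min(k, track.size - 1)])
        if f <= 0:
            raise ParameterError("frequency track must be positive")
        period = 1.0 / f
        if t + period > duration + 1e-9:
            break
        cycles.append((t, period))
        t += period
        k += 1
    return cycles


def _render_cycles(cycles: list[CycleInfo], amplitude: float, rebound_scale: float,
                   fs: float) -> np.ndarray:
    """Evaluate the piecewise cycle template on the sample grid."""
    if not cycles:
        return np.zeros(0)
    t_end = cycles[-1].start + cycles[-1].period
    n = int(np.ceil(t_end * fs - 1e-9))
    out = np.zeros(n)
    for c in cycles:
        i0 = int(np.ceil(c.start * fs - 1e-9))
        i1 = int(np.ceil((c.start + c.period) * fs - 1e-9))
        if i1 <= i0:
            continue
        u = (np.arange(i0, i1) / fs - c.start) / c.period
        y = np.zeros(u.size)
        if c.has_spike:
            y += _PT_EARLY_AMP * amplitude * np.exp(
                -0.5 * ((u - _PT_EARLY_CENTER) / _PT_EARLY_SIGMA) ** 2)
            sig_u = _SPIKE_SIGMA_S / c.period
            y -= amplitude * np.exp(-0.5 * ((u - _SPIKE_CENTER) / sig_u) ** 2)
            y += _PT_LATE_AMP * amplitude * np.exp(
                -0.5 * ((u - _PT_LATE_CENTER) / _PT_LATE_SIGMA) ** 2)
        if c.has_wave:
            m = (u >= _WAVE_NEG_START) & (u < _WAVE_NEG_START + _WAVE_NEG_WIDTH)
            y[m] -= _WAVE_NEG_AMP * amplitude * np.sin(
                np.pi * (u[m] - _WAVE_NEG_START) / _WAVE_NEG_WIDTH)
            m = (u >= _REBOUND_START) & (u < _REBOUND_START + _REBOUND_WIDTH)
            y[m] += rebound_scale * _WAVE_NEG_AMP * amplitude * np.sin(
                np.pi * (u[m] - _REBOUND_START) / _REBOUND_WIDTH)
        if c.inverted:
            y = -y
        out[i0:i1] = y
    return out


def _calibrate_rebound(cycles: list[CycleInfo], amplitude: float, fs: float,
                       target_pct: float) -> float:
    """Rebound scale for which the measured asymmetry equals the target (%)."""

    def err(s: float) -> float:
        return asymmetry_of_samples(_render_cycles(cycles, amplitude, s, fs)) - target_pct

    lo, hi = 0.0, 6.0
    if err(lo) < 0:  # even with no rebound the index is below target
        return lo
    if err(hi) > 0:
        raise ParameterError(
            f"asymmetry target {target_pct / 100:.2f} not attainable by this waveform")
    return float(brentq(err, lo, hi, xtol=1e-4))


def _build_cycles(variant: str, duration: float, freq_track, start_hz: float,
                  steady_hz: float, rng: np.random.Generator) -> list[CycleInfo]:
    if variant in ("mature", "immature"):
        schedule = _cycle_schedule(duration, freq_track, start_hz, steady_hz)
        cycles = [CycleInfo(t, T, 1.0 / T) for t, T in schedule]
        if variant == "immature":
            n = len(cycles)
            drop = np.zeros(n, dtype=bool)
            drop[rng.permutation(n)[: int(round(_IMMATURE_SPIKE_DROP * n))]] = True
            keep_wave = np.zeros(n, dtype=bool)
            keep_wave[rng.permutation(n)[: int(round(_IMMATURE_WAVE_KEEP * n))]] = True
            cycles = [
                replace(c, has_spike=not d, has_wave=bool(w))
                for c, d, w in zip(cycles, drop, keep_wave)
            ]
            if not any(c.has_spike for c in cycles):  # keep the event anchored
                cycles[0] = replace(cycles[0], has_spike=True)
        return cycles

    if variant == "fused":
        cycles: list[CycleInfo] = []
        t0 = 0.0
        remaining = duration
        while remaining > 1.0:
            chunk = min(float(rng.uniform(*_FUSED_CHUNK)), remaining)
            sub = _cycle_schedule(chunk, freq_track, start_hz, steady_hz)
            cycles.extend(CycleInfo(t0 + t, T, 1.0 / T) for t, T in sub)
            used = sum(T for _, T in sub)
            t0 += used + _FUSED_GAP
            remaining -= used + _FUSED_GAP
        return cycles

    if variant == "atypical":
        # Three-part structure: spikes-only onset at the typical rate, an
        # inverted-polarity 2.5 Hz middle, and a <1 Hz terminal part.
        cycles = []
        d1, d2 = 0.25 * duration, 0.50 * duration
        for t, T in _cycle_schedule(d1, steady_hz, start_hz, steady_hz):
            cycles.append(CycleInfo(t, T, 1.0 / T, has_spike=True, has_wave=False))
        t0 = cycles[-1].start + cycles[-1].period if cycles else 0.0
        for t, T in _cycle_schedule(d2, 2.5, start_hz, steady_hz):
            cycles.append(CycleInfo(t0 + t, T, 1.0 / T, inverted=True))
        t0 = cycles[-1].start + cycles[-1].period
        for t, T in _cycle_schedule(duration - t0, 0.8, start_hz, steady_hz):
            cycles.append(CycleInfo(t0 + t, T, 1.0 / T))
        return cycles

    raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")


def synthesize_discharge(
    variant: str,
    duration: float,
    amplitude: float,
    asymmetry: float,
    freq_track=None,
    sampling_rate: float = 400.0,
    *,
    fundamental_start_hz: float = 9.5,
    fundamental_steady_hz: float = 7.5,
    rng: np.random.Generator | None = None,
) -> DischargeSegment:
    """Render one clean discharge of the requested variant.

    Parameters
    ----------
    variant
        One of ``mature``, ``immature``, ``fused``, ``atypical``.
    duration : s
        Target duration; the rendered segment is trimmed to whole cycles, so
        the actual duration is within one cycle period below the target.
    amplitude : µV
        Spike peak deviation from baseline.
    asymmetry
        Target negative-area share in (0, 1); imposed exactly (on the clean
        segment, as measured by the package's own estimator) for mature,
        immature and fused variants; atypical discharges are built with a
        fixed near-symmetric rebound instead.
    freq_track
        ``None`` (linear settle from start to steady over the first second),
        a scalar (constant rate), or a per-cycle array of frequencies in Hz.
    """
    if variant not in VARIANTS:
        raise ParameterError(f"unknown variant {variant!r}; expected one of {VARIANTS}")
    min_dur = 5.0 if variant == "atypical" else 1.0
    if duration < min_dur:
        raise ParameterError(f"{variant} discharge requires duration >= {min_dur} s")
    if amplitude <= 0:
        raise ParameterError("amplitude must be positive")
    if not (0.0 < asymmetry < 1.0):
        raise ParameterError("asymmetry must lie in (0, 1)")
    rng = rng if rng is not None else np.random.default_rng(0)

    cycles = _build_cycles(variant, duration, freq_track,
                           fundamental_start_hz, fundamental_steady_hz, rng)
    if not cycles:
        raise ParameterError("duration too short for a single cycle")
    if variant == "atypical":
        rebound = 0.9  # near-symmetric: atypical discharges lack clear asymmetry
    else:
        rebound = _calibrate_rebound(cycles, amplitude, sampling_rate,
                                     100.0 * asymmetry)
    samples = _render_cycles(cycles, amplitude, rebound, sampling_rate)
    # Scale so the spike peak deviation from the event median (the baseline
    # the morphology estimator uses) equals the requested amplitude exactly.
    deviation = float(np.max(np.abs(samples - np.median(samples))))
    samples *= amplitude / deviation
    measured = asymmetry_of_samples(samples)
    return DischargeSegment(
        samples=samples,
        sampling_rate=sampling_rate,
        cycles=tuple(cycles),
        variant=variant,
        amplitude=amplitude,
        asymmetry_measured=measured,
    )


def _pack_onsets(rng: np.random.Generator, durations: np.ndarray, session: float,
                 min_gap: float) -> np.ndarray:
    """Uniform random onsets with all inter-event (and edge) gaps >= min_gap.

    Sampled exactly over the feasible set: the slack left after subtracting
    event durations and mandatory gaps is split by sorted uniform draws and
    re-inserted, which is the standard measure-preserving reduction and never
    needs rejection.  Infeasible requests raise :class:`PackingError`.
    """
    n = durations.size
    slack = session - durations.sum() - (n + 1) * min_gap
    if slack < 0:
        raise PackingError(
            f"cannot place {n} events totalling {durations.sum():.1f} s with "
            f"min_gap={min_gap} s in {session} s"
        )
    extra = np.sort(rng.uniform(0.0, slack, n))
    starts = min_gap + extra + np.concatenate([[0.0], np.cumsum(durations[:-1] + min_gap)])
    return starts


def generate_session(config: GeneratorConfig) -> tuple[EEGRecording, list[SWDAnnotation]]:
    """One annotated session: background plus ``swd_count`` injected discharges.

    Returns the recording and a sorted, non-overlapping list of ground-truth
    annotations.  Bit-identical for identical configs (all randomness derives
    from ``config.seed``).
    """
    fs = config.sampling_rate
    ss = np.random.SeedSequence(config.seed)
    bg_seed, pack_seed, ev_seed = ss.spawn(3)
    recording = generate_background(config, config.session_length,
                                    rng=np.random.default_rng(bg_seed))
    samples = recording.samples.copy()
    annotations: list[SWDAnnotation] = []

    if config.swd_count > 0:
        rng_pack = np.random.default_rng(pack_seed)
        lo, hi = config.swd_duration_range
        durations = rng_pack.uniform(lo, hi, config.swd_count)
        names = sorted(config.variant_mix)
        probs = np.array([config.variant_mix[v] for v in names])
        variants = rng_pack.choice(names, size=config.swd_count, p=probs / probs.sum())
        onsets = _pack_onsets(rng_pack, durations, config.session_length, config.min_gap)

        rng_events = np.random.default_rng(ev_seed)
        for onset, dur, variant in zip(onsets, durations, variants):
            variant = str(variant)
            seg = synthesize_discharge(
                variant, float(dur), config.swd_amplitude, config.asymmetry,
                sampling_rate=fs,
                fundamental_start_hz=config.fundamental_start_hz,
                fundamental_steady_hz=config.fundamental_steady_hz,
                rng=rng_events,
            )
            i0 = int(round(onset * fs))
            i1 = i0 + seg.samples.size
            samples[0, i0:i1] = seg.samples  # discharge replaces background
            annotations.append(SWDAnnotation(
                onset=i0 / fs,
                offset=i1 / fs,
                variant=variant,
                true_amplitude=config.swd_amplitude,
                true_asymmetry=seg.asymmetry_measured,
                true_frequency_track=tuple(c.frequency for c in seg.cycles),
            ))

    out = EEGRecording(samples, fs, recording.channel_labels)
    return out, sorted(annotations, key=lambda a: a.onset)
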