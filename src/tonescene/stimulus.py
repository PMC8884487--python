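"""Temporal-coherence figure-ground stimulus synthesis.

A trial is a 4-s cloud of 20 amplitude-modulated tones.  During two 1-s
"coherent" periods (seconds 1-2 and 3-4) a subset of N tones shares a single
envelope realisation, binding them into a perceptual foreground figure; in
the remaining periods every tone is modulated independently.  Because every
tone keeps the same modulation statistics throughout, the only figure cue is
the across-channel coherence itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .envelope import EnvelopeParams, synth_envelope
from .erb import ToneBank, erb_number, place_tones

__all__ = [
    "CoherenceSchedule",
    "TrialStimulus",
    "SessionLog",
    "SeparationVariantSpec",
    "make_trial",
    "make_session",
    "make_separation_variant",
    "write_wav",
    "read_wav",
    "write_event_log",
    "read_event_log",
]

#: dB SPL assigned to a digital waveform of RMS 1.0 (calibration convention).
FULL_SCALE_DB_SPL = 100.0


@dataclass(frozen=True)
class CoherenceSchedule:
    """Segment boundaries and which tones are coherent in which segment.

    ``boundaries_s`` splits the trial into segments; ``coherent_segments``
    lists the indices of segments (0-based) in which the coherent subset
    shares an envelope.  Defaults give the alternating
    incoherent/coherent/incoherent/coherent structure.
    """

    coherent_tone_indices: np.ndarray
    boundaries_s: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    )
    coherent_segments: tuple[int, ...] = (1, 3)

    def __post_init__(self):
        idx = np.asarray(self.coherent_tone_indices, dtype=int)
        if idx.size != np.unique(idx).size:
            raise ValueError("coherent tone indices must be unique")
        b = np.asarray(self.boundaries_s, dtype=float)
        if np.any(np.diff(b) <= 0):
            raise ValueError("segment boundaries must be strictly increasing")
        if any(s >= b.size - 1 for s in self.coherent_segments):
            raise ValueError("coherent segment index out of range")
        object.__setattr__(self, "coherent_tone_indices", idx)
        object.__setattr__(self, "boundaries_s", b)

    @property
    def n_coherent(self) -> int:
        return int(self.coherent_tone_indices.size)

    @property
    def n_segments(self) -> int:
        return int(self.boundaries_s.size - 1)

    @property
    def duration_s(self) -> float:
        return float(self.boundaries_s[-1] - self.boundaries_s[0])

    @property
    def event_times_s(self) -> np.ndarray:
        """Onsets of the coherent segments (the coherence-change events)."""
        return self.boundaries_s[list(self.coherent_segments)]

    @staticmethod
    def random_subset(
        n_coherent: int, n_tones: int, rng: np.random.Generator
    ) -> "CoherenceSchedule":
        """Default schedule with a randomly drawn coherent subset."""
        if n_coherent > n_tones:
            raise ValueError("cannot make more tones coherent than exist")
        idx = np.sort(rng.choice(n_tones, size=n_coherent, replace=False))
        return CoherenceSchedule(idx)


@dataclass
class TrialStimulus:
    """One synthesised trial: waveform, envelopes and coherence metadata.

    ``per_tone_envelopes`` is stored at the (lower) envelope sampling rate;
    the audio waveform uses linearly interpolated copies of these envelopes.
    """

    waveform: np.ndarray
    sample_rate_hz: float
    schedule: CoherenceSchedule
    per_tone_envelopes: np.ndarray  # (n_tones, n_env_samples)
    envelope_rate_hz: float
    bank: ToneBank
    seed: int | None = None

    @property
    def duration_s(self) -> float:
        return self.waveform.size / self.sample_rate_hz

    @property
    def event_times_s(self) -> np.ndarray:
        return self.schedule.event_times_s

    def envelope_times_s(self) -> np.ndarray:
        return np.arange(self.per_tone_envelopes.shape[1]) / self.envelope_rate_hz


def _segment_envelopes(
    bank: ToneBank,
    env: EnvelopeParams,
    schedule: CoherenceSchedule,
    rng: np.random.Generator,
    crossfade_s: float,
) -> np.ndarray:
    """Per-tone envelopes across all segments, with optional crossfading.

    Each segment gets fresh realisations; within a coherent segment the
    coherent subset shares one realisation (a new one per coherent period).
    Crossfades occupy the last ``crossfade_s`` of each non-final segment, so
    the interior of every segment is an unblended realisation.
    """
    n_tones = bank.n_tones
    fs = env.sample_rate_hz
    bounds = np.round(schedule.boundaries_s * fs).astype(int)
    n_total = bounds[-1] - bounds[0]
    out = np.zeros((n_tones, n_total))
    n_xf = int(round(crossfade_s * fs))
    coh = set(schedule.coherent_tone_indices.tolist())

    seg_envs: list[np.ndarray] = []
    for s in range(schedule.n_segments):
        seg_len = bounds[s + 1] - bounds[s]
        dur = seg_len / fs
        block = np.empty((n_tones, seg_len))
        if s in schedule.coherent_segments and coh:
            shared = synth_envelope(env, dur, rng)
            for i in range(n_tones):
                block[i] = shared if i in coh else synth_envelope(env, dur, rng)
        else:
            for i in range(n_tones):
                block[i] = synth_envelope(env, dur, rng)
        seg_envs.append(block)

    for s, block in enumerate(seg_envs):
        i0, i1 = bounds[s] - bounds[0], bounds[s + 1] - bounds[0]
        out[:, i0:i1] = block
        if n_xf > 0 and s + 1 < len(seg_envs):
            # amplitude-complementary raised-cosine blend just before boundary
            ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_xf) / n_xf))
            head = seg_envs[s + 1][:, :n_xf]
            out[:, i1 - n_xf : i1] = (1.0 - ramp) * block[:, -n_xf:] + ramp * head
    return out


def make_trial(
    bank: ToneBank,
    env: EnvelopeParams,
    schedule: CoherenceSchedule,
    seed: int | None = None,
    audio_rate_hz: float = 48000.0,
    crossfade_s: float = 0.010,
    rng: np.random.Generator | None = None,
) -> TrialStimulus:
    """Synthesise one trial.

    The waveform is the sum over tones of ``envelope_i(t) * sin(2*pi*f_i*t
    + phi_i)`` with random carrier phases, each tone scaled to its nominal
    level under the full-scale calibration convention.
    """
    if schedule.n_coherent > bank.n_tones:
        raise ValueError("n_coherent exceeds tone count")
    if audio_rate_hz <= 2 * bank.frequencies_hz[-1]:
        raise ValueError("audio rate must exceed twice the highest carrier")
    if rng is None:
        rng = np.random.default_rng(seed)

    envs = _segment_envelopes(bank, env, schedule, rng, crossfade_s)
    n_audio = int(round(schedule.duration_s * audio_rate_hz))
    t = np.arange(n_audio) / audio_rate_hz
    t_env = np.arange(envs.shape[1]) / env.sample_rate_hz
    phases = rng.uniform(0.0, 2.0 * np.pi, bank.n_tones)
    tone_rms = 10.0 ** ((bank.per_tone_level_db - FULL_SCALE_DB_SPL) / 20.0)

    wave = np.zeros(n_audio)
    for i, f in enumerate(bank.frequencies_hz):
        e = np.interp(t, t_env, envs[i])
        comp = e * np.sin(2.0 * np.pi * f * t + phases[i])
        rms = np.sqrt(np.mean(comp**2))
        if rms > 0:
            comp *= tone_rms / rms
        wave += comp
    return TrialStimulus(
        waveform=wave,
        sample_rate_hz=audio_rate_hz,
        schedule=schedule,
        per_tone_envelopes=envs,
        envelope_rate_hz=env.sample_rate_hz,
        bank=bank,
        seed=seed,
    )


@dataclass
class SessionLog:
    """Tabular record of a stimulus session (one row per trial)."""

    records: pd.DataFrame
    master_seed: int

    COLUMNS = ("trial_id", "condition_N", "onset_s", "isi_s", "coherent_indices", "seed")

    def counts_per_condition(self) -> pd.Series:
        return self.records["condition_N"].value_counts().sort_index()

    def __len__(self) -> int:
        return len(self.records)


def make_session(
    bank: ToneBank,
    env: EnvelopeParams,
    conditions: tuple[int, ...] = (6, 12, 18),
    trials_per_condition: int = 240,
    isi_lo_s: float = 1.2,
    isi_hi_s: float = 1.3,
    seed: int = 0,
    trial_duration_s: float = 4.0,
    out_dir: str | Path | None = None,
    audio_rate_hz: float = 48000.0,
) -> SessionLog:
    """Plan (and optionally render) a session of pseudo-randomly interleaved trials.

    Returns the session log; per-trial WAV files are written only when
    ``out_dir`` is given, since a full session is large.  Every trial's
    coherent subset and envelope realisations are random from trial to
    trial, reproducible from the per-trial seeds recorded in the log.
    """
    if trials_per_condition < 1:
        raise ValueError("need at least one trial per condition")
    if isi_lo_s > isi_hi_s:
        raise ValueError("isi_lo must not exceed isi_hi")
    rng = np.random.default_rng(seed)
    order = np.repeat(list(conditions), trials_per_condition)
    rng.shuffle(order)
    n = order.size
    isis = rng.uniform(isi_lo_s, isi_hi_s, n)
    trial_seeds = rng.integers(0, 2**31 - 1, n)

    rows, onset = [], 0.0
    for k in range(n):
        trng = np.random.default_rng(int(trial_seeds[k]))
        sched = CoherenceSchedule.random_subset(int(order[k]), bank.n_tones, trng)
        rows.append(
            {
                "trial_id": k,
                "condition_N": int(order[k]),
                "onset_s": onset,
                "isi_s": float(isis[k]),
                "coherent_indices": ",".join(map(str, sched.coherent_tone_indices)),
                "seed": int(trial_seeds[k]),
            }
        )
        onset += trial_duration_s + float(isis[k])
        if out_dir is not None:
            stim = synthesize_logged_trial(rows[-1], bank, env, audio_rate_hz)
            write_wav(stim, Path(out_dir) / f"trial_{k:04d}.wav")
    return SessionLog(pd.DataFrame(rows, columns=list(SessionLog.COLUMNS)), seed)


def synthesize_logged_trial(
    row, bank: ToneBank, env: EnvelopeParams, audio_rate_hz: float = 48000.0
) -> TrialStimulus:
    """Re-synthesise one trial bit-identically from its session-log row."""
    seed = int(row["seed"])
    trng = np.random.default_rng(seed)
    sched = CoherenceSchedule.random_subset(int(row["condition_N"]), bank.n_tones, trng)
    return make_trial(bank, env, sched, seed=seed, audio_rate_hz=audio_rate_hz, rng=trng)


@dataclass(frozen=True)
class SeparationVariantSpec:
    """Near-threshold variants: same tone count, different frequency spread.

    ``narrow`` picks contiguous tones (~1.5 ERB apart); ``wide`` picks
    evenly strided, interspersed tones.  ``stride`` defaults to the largest
    feasible even stride for the requested subset size.
    """

    n_coherent: int = 6
    separation_mode: str = "narrow"
    stride: int | None = None

    def __post_init__(self):
        if self.separation_mode not in ("narrow", "wide"):
            raise ValueError("separation_mode must be 'narrow' or 'wide'")
        if self.n_coherent < 2:
            raise ValueError("need at least 2 coherent tones")


def variant_indices(
    spec: SeparationVariantSpec, n_tones: int, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Tone indices for a separation variant (centred in the bank)."""
    m = spec.n_coherent
    if spec.separation_mode == "narrow":
        start = (n_tones - m) // 2
        return np.arange(start, start + m)
    stride = spec.stride
    if stride is None:
        stride = (n_tones - 1) // (m - 1)
    span = (m - 1) * stride
    if stride < 2 or span > n_tones - 1:
        raise ValueError(
            f"wide spread infeasible: {m} tones at stride {stride} "
            f"need a span of {span} within {n_tones} tones"
        )
    start = (n_tones - 1 - span) // 2
    return start + stride * np.arange(m)


def make_separation_variant(
    spec: SeparationVariantSpec,
    bank: ToneBank,
    env: EnvelopeParams,
    seed: int | None = None,
    audio_rate_hz: float = 48000.0,
) -> TrialStimulus:
    """Synthesise one trial of a narrow- or wide-separation variant.

    Both modes carry the same number of coherent tones, hence the same
    broadband amplitude statistics; only the tonotopic layout of the
    coherent channels differs.
    """
    idx = variant_indices(spec, bank.n_tones)
    sched = CoherenceSchedule(idx)
    return make_trial(bank, env, sched, seed=seed, audio_rate_hz=audio_rate_hz)


def realized_separation_erb(indices: np.ndarray, bank: ToneBank) -> float:
    """Mean adjacent separation, in ERB units, of the selected tones."""
    e = erb_number(bank.frequencies_hz[np.asarray(indices, dtype=int)], bank.scale)
    return float(np.mean(np.diff(e)))


def write_wav(stimulus: TrialStimulus, path: str | Path) -> Path:
    """Write the waveform as an IEEE-float32 WAV file."""
    path = Path(path)
    wavfile.write(path, int(stimulus.sample_rate_hz), stimulus.waveform.astype(np.float32))
    return path


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a float WAV back as (samples, sample_rate)."""
    rate, data = wavfile.read(path)
    return np.asarray(data), float(rate)


def write_event_log(log: SessionLog, path: str | Path) -> Path:
    path = Path(path)
    log.records.to_csv(path, sep="\t", index=False)
    return path


def read_event_log(path: str | Path, master_seed: int = -1) -> SessionLog:
    df = pd.read_csv(path, sep="\t", dtype={"coherent_indices": str})
    return SessionLog(df, master_seed)


def default_bank() -> ToneBank:
    """The standard 20-tone, 200 Hz - 8 kHz, 60 dB SPL bank."""
    return place_tones(20, 200.0, 8000.0, 60.0)
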