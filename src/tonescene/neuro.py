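"""Synthetic two-group cohorts of auditory-cortex ROI time courses.

Emulates the neural-response structure of a passive figure-ground MEG
experiment in school-aged children: a typically developing (TD) group and
an autism spectrum disorder (ASD) group, three coherence conditions
(N = 6, 12, 18 of 20 tones), and per-trial source time courses containing

* an M1 evoked component (~100 ms) and a slower M2 component (250-450 ms)
  whose amplitude grows with coherence -- growth shallower in ASD and the
  M2 strongly attenuated there;
* late (>400 ms) induced 30-70 Hz gamma with random phase per trial,
  present only in TD at the highest coherence by default;
* 1/f background noise and participant/trial-level amplitude variability;
* behavioural scores (SRS-SCI, SPQ-APS, ICSS-I, age) whose correlation
  with the latent neural effect mirrors the reported structure.

Everything is reproducible from the cohort's master seed; epochs are
synthesised lazily so full-size cohorts never need to sit in memory.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "CohortSpec",
    "ResponseModelParams",
    "BehaviorParams",
    "ParticipantRecord",
    "EpochSet",
    "Cohort",
    "simulate_participant",
    "simulate_epochs",
    "simulate_cohort",
]


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: group sizes, conditions, trial counts, epoching."""

    n_td: int = 26
    n_asd: int = 21
    conditions: tuple[int, ...] = (6, 12, 18)
    trials_per_condition: int = 60  # desk default; the full session has 240
    sample_rate_hz: float = 1000.0
    epoch_window_s: tuple[float, float] = (-0.5, 1.0)
    master_seed: int = 0

    def __post_init__(self):
        if self.n_td < 1 or self.n_asd < 1:
            raise ValueError("need at least one participant per group")
        lo, hi = self.epoch_window_s
        if not (lo <= -0.2 and hi >= 0.45):
            raise ValueError("epoch window must contain [-0.2, 0.45] s")

    @property
    def n_participants(self) -> int:
        return self.n_td + self.n_asd

    @property
    def times_s(self) -> np.ndarray:
        lo, hi = self.epoch_window_s
        n = int(round((hi - lo) * self.sample_rate_hz))
        return lo + np.arange(n) / self.sample_rate_hz


@dataclass(frozen=True)
class ResponseModelParams:
    """Shape and effect-size parameters of the simulated neural response.

    Amplitudes are in arbitrary source units.  The per-trial evoked
    amplitude is ``baseline_amp + slope[group] * rank(N) + participant
    effect + trial noise`` (rank 0, 1, 2 for N = 6, 12, 18); the M2 wave is
    additionally scaled by ``m2_atten_asd`` in the ASD group.  Defaults are
    calibrated so the full-scale N = 18 between-group contrast lands near
    t ~ 3.5 (see docs/methods.md).
    """

    m1_latency_s: float = 0.100
    m1_width_s: float = 0.020
    m2_window_s: tuple[float, float] = (0.25, 0.45)
    m2_relative_amp: float = 0.6
    baseline_amp: float = 2.0
    slope_td: float = 0.45
    slope_asd: float = 0.15
    m2_atten_asd: float = 0.40
    gamma_band_hz: tuple[float, float] = (30.0, 70.0)
    gamma_onset_s: float = 0.400
    gamma_offset_s: float = 0.900
    gamma_amp_td_n18: float = 2.2
    gamma_amp_other: float = 0.0
    noise_exponent: float = 1.0
    noise_rms: float = 5.0
    trial_noise_sd: float = 0.5
    participant_sd: float = 1.6
    random_orientation: bool = True

    def __post_init__(self):
        if self.slope_td <= self.slope_asd:
            raise ValueError("defaults require TD slope > ASD slope")

    def evoked_amp_mean(self, group: str, condition_rank: int) -> float:
        slope = self.slope_td if group == "TD" else self.slope_asd
        return self.baseline_amp + slope * condition_rank

    def gamma_amp(self, group: str, condition_n: int) -> float:
        if group == "TD" and condition_n == 18:
            return self.gamma_amp_td_n18
        return self.gamma_amp_other


@dataclass(frozen=True)
class BehaviorParams:
    """Linear generative models of the behavioural scores.

    Group means/SDs follow the reported phenotype table; within ASD the
    SRS-SCI loads negatively and the SPQ-APS positively on the latent
    neural effect, SPQ-APS drifts weakly down with age, and the ICSS-I is
    independent of the neural effect in both groups.
    """

    srs_mean_asd: float = 74.6
    srs_sd_asd: float = 11.5
    srs_loading_asd: float = -6.9  # per SD of latent effect
    srs_mean_td: float = 45.2
    srs_sd_td: float = 5.6
    spq_mean_asd: float = 15.35
    spq_sd_asd: float = 4.5
    spq_loading_asd: float = 2.25
    spq_age_slope: float = -0.5  # per year, within ASD
    spq_mean_td: float = 22.1
    spq_sd_td: float = 2.55
    icss_mean_asd: float = 8.62
    icss_sd_asd: float = 4.1
    icss_mean_td: float = 10.32
    icss_sd_td: float = 4.2
    age_range_years: tuple[float, float] = (7.0, 17.0)
    srs_range: tuple[float, float] = (30.0, 90.0)
    spq_range: tuple[float, float] = (0.0, 25.0)
    icss_range: tuple[float, float] = (1.0, 19.0)

    def _noise_sd(self, total_sd: float, *loadings: float) -> float:
        explained = sum(l * l for l in loadings)
        return float(np.sqrt(max(total_sd**2 - explained, 0.0)))


@dataclass
class ParticipantRecord:
    """One simulated participant: phenotype plus latent neural effect."""

    participant_id: str
    group: str  # "TD" or "ASD"
    age_years: float
    srs_sci: float
    spq_aps: float
    icss_i: float
    latent_effect: float  # standardised participant neural effect
    participant_effect: float  # latent * participant_sd, in amplitude units
    orientation: int  # +-1 source-dipole orientation
    seed: int


@dataclass
class EpochSet:
    """Event-locked epochs for one participant and condition.

    ``data`` has shape (n_trials, 2 events, 2 hemispheres, n_times); the
    time axis is relative to the coherence-change onset.
    """

    data: np.ndarray
    times_s: np.ndarray
    sample_rate_hz: float
    condition_n: int
    participant_id: str
    group: str

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


def _participant_seed(master_seed: int, index: int) -> int:
    ss = np.random.SeedSequence([master_seed, index])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def simulate_participant(
    spec: CohortSpec,
    params: ResponseModelParams,
    group: str,
    seed: int,
    participant_id: str | None = None,
    behavior: BehaviorParams | None = None,
) -> ParticipantRecord:
    """Draw one participant's phenotype and latent neural effect."""
    if group not in ("TD", "ASD"):
        raise ValueError("group must be 'TD' or 'ASD'")
    bp = behavior or BehaviorParams()
    rng = np.random.default_rng(seed)
    age = float(rng.uniform(*bp.age_range_years))
    latent = float(rng.standard_normal())
    mid_age = 0.5 * (bp.age_range_years[0] + bp.age_range_years[1])

    if group == "ASD":
        srs = bp.srs_mean_asd + bp.srs_loading_asd * latent + rng.normal(
            0.0, bp._noise_sd(bp.srs_sd_asd, bp.srs_loading_asd)
        )
        age_sd = (bp.age_range_years[1] - bp.age_range_years[0]) / np.sqrt(12.0)
        spq = (
            bp.spq_mean_asd
            + bp.spq_loading_asd * latent
            + bp.spq_age_slope * (age - mid_age)
            + rng.normal(
                0.0,
                bp._noise_sd(
                    bp.spq_sd_asd, bp.spq_loading_asd, bp.spq_age_slope * age_sd
                ),
            )
        )
        icss = rng.normal(bp.icss_mean_asd, bp.icss_sd_asd)
    else:
        srs = rng.normal(bp.srs_mean_td, bp.srs_sd_td)
        spq = rng.normal(bp.spq_mean_td, bp.spq_sd_td)
        icss = rng.normal(bp.icss_mean_td, bp.icss_sd_td)

    orientation = int(rng.choice([-1, 1])) if params.random_orientation else 1
    return ParticipantRecord(
        participant_id=participant_id or f"{group}_{seed}",
        group=group,
        age_years=age,
        srs_sci=float(np.clip(srs, *bp.srs_range)),
        spq_aps=float(np.clip(spq, *bp.spq_range)),
        icss_i=float(np.clip(icss, *bp.icss_range)),
        latent_effect=latent,
        participant_effect=latent * params.participant_sd,
        orientation=orientation,
        seed=seed,
    )


def _one_over_f_noise(
    n_epochs: int, n_times: int, fs: float, exponent: float, rms: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian noise with a 1/f**exponent power spectrum, target RMS."""
    freqs = np.fft.rfftfreq(n_times, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (
        rng.standard_normal((n_epochs, freqs.size))
        + 1j * rng.standard_normal((n_epochs, freqs.size))
    ) * shape
    x = np.fft.irfft(spec, n_times, axis=-1)
    x *= rms / np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    return x


def _gamma_burst(
    n_epochs: int,
    times: np.ndarray,
    fs: float,
    band: tuple[float, float],
    onset_s: float,
    offset_s: float,
    amp: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Band-limited bursts with random phase per epoch (induced activity)."""
    n_times = times.size
    freqs = np.fft.rfftfreq(n_times, d=1.0 / fs)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    spec = (
        rng.standard_normal((n_epochs, freqs.size))
        + 1j * rng.standard_normal((n_epochs, freqs.size))
    )
    spec[:, ~mask] = 0.0
    x = np.fft.irfft(spec, n_times, axis=-1)
    win = ((times >= onset_s) & (times < offset_s)).astype(float)
    # 20-ms cosine edges to avoid broadband clicks
    edge = int(round(0.020 * fs))
    rise = np.where(np.diff(np.concatenate([[0.0], win])) > 0)[0]
    for r in rise:
        win[r : r + edge] *= 0.5 * (1 - np.cos(np.pi * np.arange(edge) / edge))
    fall = np.where(np.diff(np.concatenate([win, [0.0]])) < 0)[0]
    for f in fall:
        lo = max(f - edge + 1, 0)
        win[lo : f + 1] *= 0.5 * (1 - np.cos(np.pi * np.arange(f + 1 - lo)[::-1] / edge))
    inside = win > 0.5
    if inside.any():
        x *= amp / np.sqrt(np.mean(x[:, inside] ** 2, axis=-1, keepdims=True))
    return x * win


def evoked_template(
    times: np.ndarray, params: ResponseModelParams, m2_scale: float = 1.0
) -> np.ndarray:
    """Unit-amplitude evoked waveform: M1 Gaussian pulse + M2 half-sine."""
    m1 = np.exp(-0.5 * ((times - params.m1_latency_s) / params.m1_width_s) ** 2)
    lo, hi = params.m2_window_s
    m2 = np.where(
        (times >= lo) & (times < hi),
        np.sin(np.pi * (times - lo) / (hi - lo)),
        0.0,
    )
    return m1 + m2_scale * params.m2_relative_amp * m2


def simulate_epochs(
    record: ParticipantRecord,
    spec: CohortSpec,
    params: ResponseModelParams,
    condition_n: int,
    seed: int | None = None,
) -> EpochSet:
    """Simulate all epochs of one participant in one condition.

    Each epoch is 1/f background + deterministic evoked template scaled by
    the trial's amplitude + (optionally) a random-phase gamma burst.  The
    trial amplitude is shared across the trial's two events and both
    hemispheres; background and gamma are independent per epoch.
    """
    if condition_n not in spec.conditions:
        raise ValueError(f"condition {condition_n} not in cohort spec")
    rank = spec.conditions.index(condition_n)
    rng = np.random.default_rng(record.seed + 7919 * rank if seed is None else seed)
    times = spec.times_s
    nt, n_times = spec.trials_per_condition, times.size
    n_ep = nt * 2 * 2

    m2_scale = params.m2_atten_asd if record.group == "ASD" else 1.0
    template = evoked_template(times, params, m2_scale)
    amp = (
        params.evoked_amp_mean(record.group, rank)
        + record.participant_effect
        + params.trial_noise_sd * rng.standard_normal(nt)
    )
    evoked = amp[:, None, None, None] * template * record.orientation

    noise = _one_over_f_noise(
        n_ep, n_times, spec.sample_rate_hz, params.noise_exponent, params.noise_rms, rng
    ).reshape(nt, 2, 2, n_times)

    data = evoked + noise
    g_amp = params.gamma_amp(record.group, condition_n)
    if g_amp > 0:
        data += _gamma_burst(
            n_ep, times, spec.sample_rate_hz, params.gamma_band_hz,
            params.gamma_onset_s, params.gamma_offset_s, g_amp, rng,
        ).reshape(nt, 2, 2, n_times)
    return EpochSet(
        data=data,
        times_s=times,
        sample_rate_hz=spec.sample_rate_hz,
        condition_n=condition_n,
        participant_id=record.participant_id,
        group=record.group,
    )


@dataclass
class Cohort:
    """A simulated cohort: participant table plus lazily generated epochs."""

    spec: CohortSpec
    params: ResponseModelParams
    records: list[ParticipantRecord]

    @property
    def participants(self) -> pd.DataFrame:
        rows = [
            {
                "participant_id": r.participant_id,
                "group": r.group,
                "age_years": r.age_years,
                "srs_sci": r.srs_sci,
                "spq_aps": r.spq_aps,
                "icss_i": r.icss_i,
                "latent_effect": r.latent_effect,
                "seed": r.seed,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows)

    def epochs(self, participant_id: str, condition_n: int) -> EpochSet:
        rec = next(r for r in self.records if r.participant_id == participant_id)
        return simulate_epochs(rec, self.spec, self.params, condition_n)

    def iter_epoch_sets(self):
        for rec in self.records:
            for n in self.spec.conditions:
                yield simulate_epochs(rec, self.spec, self.params, n)


def simulate_cohort(
    spec: CohortSpec,
    params: ResponseModelParams | None = None,
    behavior: BehaviorParams | None = None,
) -> Cohort:
    """Simulate a full cohort, reproducible from ``spec.master_seed``."""
    params = params or ResponseModelParams()
    records = []
    for i in range(spec.n_participants):
        group = "TD" if i < spec.n_td else "ASD"
        seed = _participant_seed(spec.master_seed, i)
        records.append(
            simulate_participant(
                spec, params, group, seed,
                participant_id=f"{group}{i:03d}", behavior=behavior,
            )
        )
    return Cohort(spec, params, records)


def null_params(params: ResponseModelParams | None = None) -> ResponseModelParams:
    """Parameters with no group differences (for type-I calibration).

    ``slope_asd`` is set equal to ``slope_td`` minus a negligible epsilon
    (the dataclass insists TD > ASD), M2 attenuation and gamma asymmetry
    are removed.
    """
    p = params or ResponseModelParams()
    return replace(
        p,
        slope_asd=p.slope_td - 1e-12,
        m2_atten_asd=1.0,
        gamma_amp_td_n18=0.0,
        gamma_amp_other=0.0,
    )
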