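# Methods

## Stimulus model

A scene is a bank of `n` pure tones placed with equal spacing on the
ERB-number scale `E(f) = 21.4·log10(4.37·f/1000 + 1)` (moderate-level
constants; pluggable via `ErbScaleParams`). With the defaults — 20 tones,
200 Hz to 8 kHz — adjacent tones sit 1.445 ERB apart, i.e. about one and a
half cochlear filter bandwidths, so neighbouring carriers interact only
weakly at the periphery. Each tone has a nominal level of 60 dB SPL under
the calibration convention that digital RMS 1.0 ≡ 100 dB SPL (absolute SPL
is a playback property; only level differences matter here). Twenty such
tones sum to ≈ 73 dB SPL.

Each tone is amplitude-modulated by an independent random envelope built
as: Gaussian white noise → ideal zero-phase band-pass 4–24 Hz (brick-wall
FFT mask, so essentially no out-of-band power) → half-wave rectification →
zero-phase Butterworth low-pass at 24 Hz → RMS normalisation. Envelopes
are synthesised at 1 kHz and linearly interpolated to the audio rate
(48 kHz by default; tests use 24 kHz, which still clears the 8-kHz
carriers).

A trial lasts exactly 4 s in 1-s segments: incoherent, coherent,
incoherent, coherent. During a coherent segment the designated subset of
*N* tones shares one envelope realisation; every other tone, and every
tone during incoherent segments, gets an independent realisation. Both
coherent periods of a trial use the same tone subset but fresh shared
realisations; subsets and envelopes are redrawn across trials. Because
every envelope is RMS-normalised per segment, within-channel modulation
statistics are constant throughout the trial — the figure exists only in
the across-channel correlation. Segment boundaries are joined by a 10-ms
raised-cosine crossfade (amplitude-complementary, placed just before each
boundary) to avoid spectral splatter; the interior of every segment is an
unblended realisation. Carrier phases are randomised per trial.

Separation variants keep the coherent-tone count fixed while moving the
subset: `narrow` picks contiguous tones (≈1.45 ERB apart), `wide` picks
evenly strided tones (largest feasible stride by default, or an explicit
stride). Matched counts mean matched broadband envelope statistics — the
variants differ only in which tonotopic channels cohere. On the default
20-tone grid the feasible wide separations are multiples of 1.445 ERB
(e.g. 5.78 ERB for 5 tones at stride 4, 8.67 ERB for 4 tones at stride 6);
the realised separation is reported rather than forced to any particular
printed value.

## Periphery audit

The validator decomposes a trial with a 4th-order complex gammatone
cascade, one channel per tone frequency, bandwidth 1 ERB (the 1.019·ERB
convention maps ERB to the gammatone's equivalent bandwidth). Envelopes
are the magnitude of the complex output, low-passed at 64 Hz, advanced by
each channel's group delay (peak of its impulse-response envelope) and
decimated to 1 kHz. Segment statistics drop 50 ms on either side of each
boundary to exclude transition transients and the crossfade zone.

The audit checks three things per trial: the per-channel RMS ratio
(coherent/incoherent periods) is centred at 1; the mean envelope
correlation among coherent-subset channel pairs far exceeds the mean
|correlation| of all other pairs; and the broadband (channel-summed)
envelope variance rises during coherent periods — envelope alignment
raises the crest of the sum even though per-channel power is unchanged.
Individual channels can show RMS ratios away from 1 through in-phase
leakage from coherent neighbours, so the pass rule constrains the
channel mean (tolerance 0.25 by default, one channel-bandwidth effect).

The model observer slides a 1-s window over the channel envelopes and
greedily grows a channel subset maximising mean pairwise correlation; the
maximum subset score over windows is a scale-free detection statistic that
rises with *N*. Adjacent-channel leakage gives a nonzero floor (~0.7 for
*N* = 0 at these filter bandwidths); only differences of the statistic are
meaningful.

## Synthetic cohort

Each participant carries: group, age ~ U(7, 17), a standard-normal latent
neural effect, a ±1 source orientation, and behavioural scores. The neural
amplitude model per trial is

```
amp = baseline_amp + slope[group]·rank(N) + participant_effect + trial_noise
```

with rank 0/1/2 for N = 6/12/18 and `participant_effect =
participant_sd · latent`. Each epoch (two per trial, two hemispheres,
−0.5…1.0 s at 1 kHz) is `orientation · amp · template(t)` plus 1/f
background noise (exponent 1, RMS 5 source units, independent per epoch)
plus — for TD at N = 18 — a 30–70 Hz band-limited burst from 400 to
900 ms with random phase per epoch (RMS 2.2 inside the burst window), so
it cancels in the trial average and survives only in per-trial spectra.
The template is an M1 Gaussian pulse (peak 100 ms, SD 20 ms) plus an M2
half-sine over 250–450 ms at 0.6 of the M1 height; the M2 part is scaled
by 0.40 in the ASD group.

Defaults (frozen after calibration): `baseline_amp 2.0`, `slope_td 0.45`,
`slope_asd 0.15`, `participant_sd 1.6`, `trial_noise_sd 0.5`,
`noise_rms 5.0`. The calibration criterion, run through the full
generator → analysis chain at 240 trials/condition, was that the N = 18
between-group contrast lands near t(45) ≈ 3.5 in expectation — an aid for
realism, not a claim the pipeline is tested against. Two facts shaped the
defaults. First, the baseline-z measure is scale-invariant, so its noise
floor (the 1/f wander of a 400-ms window mean relative to the baseline SD,
≈ 0.5 z per hemisphere pair) does not shrink with trial count; detecting
the growth-rate interaction therefore genuinely needs full-length
sessions. Second, participants whose net amplitude approaches zero get
their polarity mis-assigned by the alignment step, which inflates the
interaction error term; `baseline_amp = 2.0` keeps amplitudes positive.
The implied single-trial M1 SNR is ≈ −6 dB, our chosen value within the
plausible source-level range (true per-trial SNR and between-participant
variance are free assumptions, exposed in `ResponseModelParams`).

Behavioural scores follow the phenotype table: within ASD, SRS-SCI
(mean 74.6, SD 11.5) loads −6.9 per SD of the latent effect, SPQ-APS
(mean 15.35, SD 4.5) loads +2.25 and drifts −0.5/year with age, ICSS-I is
independent of the latent effect in both groups; TD scores are
latent-independent. Scores are clipped to instrument ranges (SRS T-score
30–90, SPQ 0–25, ICSS 1–19).

What the generator does *not* emulate: sensor-level physics and artifacts,
source-localisation error, per-participant latency differences, condition
dependence of the random effect, or non-Gaussian score distributions.
Passing tests therefore certify the analysis chain's arithmetic and its
statistical calibration under this generative family, not performance on
real MEG data.

## Analysis chain

Evoked: the two coherence-change epochs of each trial are averaged; per
hemisphere the trial-average's polarity is flipped if needed so the M1
window mean is positive; the trial average is z-scored against the 200 ms
before the event; M1 = mean z over 50–150 ms, M2 over 250–450 ms,
combined over 50–450 ms; hemispheres are averaged (scores commute with
averaging for these linear windows). Windows use half-sample tolerance so
[50, 450) ms is exactly 400 samples at 1 kHz. Zero baseline variance is an
error, not a silent NaN.

Induced: per-epoch multitaper spectrograms with 200-ms windows, 50%
overlap, and 3 orthogonal DPSS tapers. The printed taper plan ("time-
bandwidth product 4, 3 tapers") pins down the convention: 3 = 2·NW − 1
requires half-bandwidth product NW = 2, i.e. full time-bandwidth product
4; both numbers are exposed in `TaperPlan`. Power is averaged over trials
and events, log-transformed (natural log), time-collapsed separately over
the pre-event baseline (windows fully inside −0.5…0 s, the tail of the
preceding incoherent period) and the response region, and reported as the
log-ratio spectrum over 5–70 Hz; gamma power is the 30–70 Hz mean. The
per-trial-first order is essential: a random-phase burst is invisible in
the spectrogram of the trial average.

## Inference

`GroupConditionModel` fits the balanced mixed model by the stratum
decomposition: the between-participant stratum (participant means) tests
group against the participant mean square; the within-participant stratum
tests condition and interaction against the condition × participant mean
square. These are the REML/scaled-Wald F statistics for the single
random-intercept model, identical to classical repeated-measures ANOVA —
with 26 + 21 participants and 3 conditions: F(1, 45) and F(2, 90).
Variance components come from the mean squares (participant variance
clamped at zero). Unbalanced tables fall back, with a warning, to an exact
permutation test of group labels on complete cases. Condition effects are
fitted as weighted means (with unequal group sizes this is the standard
sequential decomposition; groups balanced gives the textbook answer
exactly).

Per-condition contrasts are pooled-variance two-sample t tests
(df = n₁ + n₂ − 2 = 45 at study size). The diagnosis classifier is a
linear SVM (C = 1) on the N = 18 combined-z and gamma log-ratio, features
standardised on the training fold only, over 50 repeated 90/10 splits —
by default independent re-partitions (no participant duplicated within a
split); a bootstrap-resampled variant is selectable. Splits with a
single-class training fold are redrawn. Behaviour prediction is in-sample
least squares, reporting Pearson r between fitted and observed values;
this equals the multiple correlation coefficient and is optimistically
biased at n ≈ 21 (≈ 0.3 under the null with two predictors) — documented,
deliberately not corrected, with the SPQ-APS age-residualised first.
p-values are unadjusted: these are the paradigm's planned contrasts.

## Numerical choices and degenerate inputs

* Seeds: every stage derives its stream from the master seed via
  `SeedSequence([master_seed, tag, extra])`; per-trial seeds are logged so
  any trial can be re-synthesised bit-identically.
* Problem sizes: the test suite runs stimuli at 24 kHz, Monte-Carlo audits
  at 25 trials per condition, null calibration on 500 reduced cohorts
  (10 + 8 participants, 16 trials, 250 Hz), and parameter recovery on 100
  full-trial-count cohorts at 500 Hz with a −0.25…0.5 s window — sizes
  chosen so the whole chain stays desk-runnable while each check retains
  its resolving power.
* Zero within-stratum residual yields infinite F (reported as such);
  identical groups yield t = 0, p = 1; constant age vectors centre the
  scores with a warning; n_coherent > n_tones, windows outside the epoch,
  centre frequencies at or above Nyquist, and epochs shorter than one
  spectrogram window are errors.

## Known limitations

* The wide-separation grid cannot realise arbitrary ERB separations
  (multiples of 1.445 ERB only on the default bank); realised separations
  are reported instead.
* The permutation fallback covers unbalanced tables but only the
  single-random-intercept structure; general covariance families are out
  of scope.
* The gammatone audit uses a linear periphery: no adaptation, compression
  or rate-level nonlinearity, and diotic stimuli only.
* At desk scale (60 trials/condition) the group × condition interaction is
  underpowered by design; full-length sessions are required, as with the
  real paradigm.
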