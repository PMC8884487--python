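"""Random amplitude envelopes: half-wave-rectified, smoothed band-limited noise.

Each tone in a scene is modulated by its own random envelope whose
modulation spectrum lives in the 4-24 Hz band (the range of natural speech
envelopes).  Envelopes are synthesised at a low "envelope rate" (default
1 kHz) and later interpolated to the audio rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = ["EnvelopeParams", "bandlimited_noise", "synth_envelope"]


@dataclass(frozen=True)
class EnvelopeParams:
    """Parameters of the envelope generator.

    band_lo_hz / band_hi_hz bound the modulation band of the underlying
    noise; smoothing_cutoff_hz is the post-rectification low-pass;
    sample_rate_hz is the envelope sampling rate (not the audio rate);
    normalization_target is the RMS the finished envelope is scaled to.
    """

    band_lo_hz: float = 4.0
    band_hi_hz: float = 24.0
    smoothing_cutoff_hz: float = 24.0
    sample_rate_hz: float = 1000.0
    normalization_target: float = 1.0
    filter_order: int = 6

    def __post_init__(self):
        if not (0 < self.band_lo_hz < self.band_hi_hz < self.sample_rate_hz / 2):
            raise ValueError("require 0 < band_lo < band_hi < Nyquist")


def bandlimited_noise(
    params: EnvelopeParams, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """The pre-rectification stage: zero-phase band-passed Gaussian noise.

    The band-pass is an ideal (brick-wall) zero-phase filter applied in the
    frequency domain, so essentially all pre-rectification power sits inside
    [band_lo, band_hi].  Exposed separately so the modulation-band
    concentration can be verified before rectification spreads power to
    harmonics.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration_s * params.sample_rate_hz))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / params.sample_rate_hz)
    spec[(freqs < params.band_lo_hz) | (freqs > params.band_hi_hz)] = 0.0
    return np.fft.irfft(spec, n)


def synth_envelope(
    params: EnvelopeParams, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """One random envelope realisation.

    Pipeline: Gaussian white noise -> zero-phase band-pass (band_lo..band_hi)
    -> half-wave rectification -> zero-phase low-pass smoothing -> RMS
    normalisation to ``normalization_target``.  The result is nonnegative
    and reproducible given the generator state.
    """
    x = bandlimited_noise(params, duration_s, rng)
    x = np.maximum(x, 0.0)  # half-wave rectify
    sos = signal.butter(
        params.filter_order,
        params.smoothing_cutoff_hz,
        btype="lowpass",
        fs=params.sample_rate_hz,
        output="sos",
    )
    x = signal.sosfiltfilt(sos, x)
    # smoothing can produce tiny negative undershoots; clip them away
    x = np.maximum(x, 0.0)
    rms = float(np.sqrt(np.mean(x**2)))
    if rms == 0.0:
        raise RuntimeError("degenerate all-zero envelope realisation")
    return x * (params.normalization_target / rms)
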