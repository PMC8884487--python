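"""Equivalent-rectangular-bandwidth (ERB) frequency scale and tone placement.

The ERB-number scale maps frequency to units of cochlear-filter bandwidths,
so equal steps on the scale correspond to equal numbers of auditory filters.
Tone clouds built here space their carriers uniformly on this scale, which
keeps peripheral interactions between neighbouring tones roughly constant
across the audio range.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ErbScaleParams",
    "ToneBank",
    "erb_number",
    "erb_to_hz",
    "erb_bandwidth",
    "place_tones",
    "overall_level",
]


@dataclass(frozen=True)
class ErbScaleParams:
    """Constants of the moderate-level ERB-number mapping.

    The mapping is ``E(f) = scale * log10(coeff * f_kHz + 1)`` with the
    corresponding filter bandwidth ``ERB(f) = bw_scale * (coeff * f_kHz + 1)``
    in Hz.  Defaults are the widely used moderate-level constants
    (scale 21.4, coeff 4.37 per kHz, bandwidth scale 24.7 Hz).
    """

    scale: float = 21.4
    coeff_per_khz: float = 4.37
    bw_scale_hz: float = 24.7


_DEFAULT_SCALE = ErbScaleParams()


def erb_number(frequency_hz, params: ErbScaleParams = _DEFAULT_SCALE):
    """ERB-number (dimensionless) of a frequency in Hz.

    Strictly increasing in frequency; accepts scalars or arrays.

    Raises
    ------
    ValueError
        If any frequency is nonpositive.
    """
    f = np.asarray(frequency_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    out = params.scale * np.log10(params.coeff_per_khz * f / 1000.0 + 1.0)
    return out if out.ndim else float(out)


def erb_to_hz(erb_num, params: ErbScaleParams = _DEFAULT_SCALE):
    """Inverse of :func:`erb_number`: map ERB-number back to frequency in Hz."""
    e = np.asarray(erb_num, dtype=float)
    out = (10.0 ** (e / params.scale) - 1.0) * 1000.0 / params.coeff_per_khz
    return out if out.ndim else float(out)


def erb_bandwidth(frequency_hz, params: ErbScaleParams = _DEFAULT_SCALE):
    """Equivalent rectangular bandwidth in Hz at a given centre frequency."""
    f = np.asarray(frequency_hz, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    out = params.bw_scale_hz * (params.coeff_per_khz * f / 1000.0 + 1.0)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ToneBank:
    """A bank of pure-tone carriers defining the scene.

    Parameters
    ----------
    frequencies_hz
        Strictly increasing carrier frequencies.
    per_tone_level_db
        Intensity of each tone in dB SPL (all tones share one level).
    scale
        The ERB-scale constants the bank was placed with.
    """

    frequencies_hz: np.ndarray
    per_tone_level_db: float = 60.0
    scale: ErbScaleParams = field(default=_DEFAULT_SCALE)

    def __post_init__(self):
        f = np.asarray(self.frequencies_hz, dtype=float)
        if f.size < 1:
            raise ValueError("tone bank must contain at least one tone")
        if np.any(np.diff(f) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "frequencies_hz", f)

    @property
    def n_tones(self) -> int:
        return int(self.frequencies_hz.size)

    @property
    def erb_numbers(self) -> np.ndarray:
        return erb_number(self.frequencies_hz, self.scale)

    @property
    def adjacent_spacing_erb(self) -> np.ndarray:
        """Spacing between neighbouring tones on the ERB-number scale."""
        return np.diff(self.erb_numbers)

    @property
    def overall_level_db(self) -> float:
        return overall_level(self)


def place_tones(
    count: int,
    f_lo_hz: float = 200.0,
    f_hi_hz: float = 8000.0,
    per_tone_level_db: float = 60.0,
    params: ErbScaleParams = _DEFAULT_SCALE,
) -> ToneBank:
    """Place ``count`` tones with equal ERB-number spacing between endpoints.

    The endpoints are hit exactly; with the defaults (20 tones, 200 Hz to
    8 kHz) the adjacent spacing is ~1.445 ERB, i.e. roughly one and a half
    cochlear-filter bandwidths between neighbours.
    """
    if count < 2:
        raise ValueError("need at least 2 tones to span a frequency range")
    if not (0 < f_lo_hz < f_hi_hz):
        raise ValueError("require 0 < f_lo < f_hi")
    e = np.linspace(erb_number(f_lo_hz, params), erb_number(f_hi_hz, params), count)
    freqs = erb_to_hz(e, params)
    # pin endpoints exactly against round-trip error
    freqs[0], freqs[-1] = f_lo_hz, f_hi_hz
    return ToneBank(freqs, per_tone_level_db, params)


def overall_level(bank: ToneBank) -> float:
    """Total level in dB SPL of the bank: power sum of the per-tone intensities.

    For ``n`` equal-level tones this is ``per_tone_level + 10*log10(n)``,
    e.g. 20 tones at 60 dB SPL sum to ~73 dB SPL.
    """
    if bank.n_tones < 1:
        raise ValueError("empty tone bank")
    return float(bank.per_tone_level_db + 10.0 * np.log10(bank.n_tones))
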