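"""Quick-look figures for stimuli, evoked traces and induced spectra."""

from __future__ import annotations

import numpy as np

from .evoked import baseline_zscore, collapse_events
from .induced import induced_power
from .neuro import EpochSet
from .stimulus import TrialStimulus

__all__ = ["plot_trial_envelopes", "plot_evoked", "plot_induced_spectrum"]


def plot_trial_envelopes(stim: TrialStimulus, ax=None):
    """Per-tone envelopes over time; coherent subset highlighted."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    t = stim.envelope_times_s()
    coh = set(stim.schedule.coherent_tone_indices.tolist())
    for i, e in enumerate(stim.per_tone_envelopes):
        ax.plot(t, e + 2.5 * i, lw=0.6, color="C3" if i in coh else "0.6")
    for ev in stim.event_times_s:
        ax.axvline(ev, color="k", ls="--", lw=0.8)
    ax.set(xlabel="time (s)", ylabel="tone index (offset)", yticks=[])
    return ax


def plot_evoked(epochs: EpochSet, ax=None):
    """Baseline z-scored, event-collapsed trial average."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    collapsed, _ = collapse_events(epochs)
    z = baseline_zscore(collapsed.mean(axis=0), epochs.times_s)
    for h in range(z.shape[0]):
        ax.plot(epochs.times_s, z[h], label=f"hemisphere {h}")
    ax.axvspan(0.05, 0.15, alpha=0.15, color="C0", label="M1 window")
    ax.axvspan(0.25, 0.45, alpha=0.15, color="C1", label="M2 window")
    ax.set(xlabel="time re coherence change (s)", ylabel="z")
    ax.legend(fontsize=8)
    return ax


def plot_induced_spectrum(epochs: EpochSet, ax=None):
    """Baseline-referenced induced log-power spectrum, 5-70 Hz."""
    import matplotlib.pyplot as plt

    ax = ax or plt.gca()
    spec = induced_power(epochs)
    ax.plot(spec.index.values, spec.values)
    ax.axvspan(30, 70, alpha=0.1, color="C2", label="gamma band")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set(xlabel="frequency (Hz)", ylabel="log power re baseline")
    ax.legend(fontsize=8)
    return ax
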