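"""Evoked-response quantification: event collapsing, baseline z-scoring,
component-window means.

The quantification chain mirrors standard source-space MEG practice: the
two coherence-change events of each trial are averaged into one epoch, the
trial average is z-scored against the 200 ms immediately preceding the
event, and the M1 (50-150 ms), M2 (250-450 ms) and combined (50-450 ms)
windows are summarised by their mean z.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .neuro import Cohort, EpochSet

__all__ = [
    "collapse_events",
    "baseline_zscore",
    "window_scores",
    "evoked_summary",
    "M1_WINDOW_S",
    "M2_WINDOW_S",
    "COMBINED_WINDOW_S",
]

M1_WINDOW_S = (0.050, 0.150)
M2_WINDOW_S = (0.250, 0.450)
COMBINED_WINDOW_S = (0.050, 0.450)
BASELINE_WINDOW_S = (-0.200, 0.0)


def _window_mask(times: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    dt = times[1] - times[0] if times.size > 1 else 0.0
    if lo < times[0] - 1e-9 or hi > times[-1] + 1.5 * dt + 1e-12:
        raise ValueError(f"window {window} outside epoch [{times[0]}, {times[-1]}]")
    # half-sample tolerance keeps [lo, hi) exactly hi-lo seconds of samples
    return (times > lo - 0.5 * dt) & (times < hi - 0.5 * dt)


def collapse_events(
    epochs: EpochSet, align_polarity: bool = True
) -> tuple[np.ndarray, np.ndarray]:
    """Average the two coherence-change events of each trial.

    Returns ``(collapsed, sign)`` where ``collapsed`` has shape
    (n_trials, n_hemispheres, n_times).  With ``align_polarity`` the sign
    of each hemisphere's trial-average trace is flipped if needed so the
    M1-window mean is positive (source dipole orientation is arbitrary);
    the chosen signs are returned.
    """
    if epochs.data.ndim != 4 or epochs.data.shape[1] != 2:
        raise ValueError("expected epochs shaped (trials, 2 events, hemis, times)")
    collapsed = epochs.data.mean(axis=1)  # (trials, hemis, times)
    n_hemi = collapsed.shape[1]
    sign = np.ones(n_hemi)
    if align_polarity:
        m1 = _window_mask(epochs.times_s, M1_WINDOW_S)
        avg = collapsed.mean(axis=0)  # (hemis, times)
        sign = np.where(avg[:, m1].mean(axis=1) >= 0, 1.0, -1.0)
        collapsed = collapsed * sign[None, :, None]
    return collapsed, sign


def baseline_zscore(
    trace: np.ndarray,
    times_s: np.ndarray,
    baseline_window_s: tuple[float, float] = BASELINE_WINDOW_S,
) -> np.ndarray:
    """Z-score a trace (or stack of traces) against its pre-event baseline.

    The baseline mean and SD are computed over ``baseline_window_s``
    (default the 200 ms before the event) along the last axis.
    """
    mask = _window_mask(times_s, baseline_window_s)
    base = trace[..., mask]
    mu = base.mean(axis=-1, keepdims=True)
    sd = base.std(axis=-1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero baseline variance; cannot z-score")
    return (trace - mu) / sd


def window_scores(
    z_trace: np.ndarray,
    times_s: np.ndarray,
    average_hemispheres: bool = True,
) -> dict[str, float]:
    """M1 / M2 / combined window means of a z-scored trace.

    ``z_trace`` may be (n_times,) or (n_hemispheres, n_times); with
    ``average_hemispheres`` the per-hemisphere scores are averaged.
    """
    z = np.atleast_2d(np.asarray(z_trace, dtype=float))
    out = {}
    for name, win in (
        ("m1_z", M1_WINDOW_S),
        ("m2_z", M2_WINDOW_S),
        ("combined_z", COMBINED_WINDOW_S),
    ):
        mask = _window_mask(times_s, win)
        per_hemi = z[:, mask].mean(axis=1)
        out[name] = float(per_hemi.mean()) if average_hemispheres else per_hemi
    return out


def evoked_epoch_scores(epochs: EpochSet, align_polarity: bool = True) -> dict[str, float]:
    """Full evoked chain for one participant x condition."""
    collapsed, _ = collapse_events(epochs, align_polarity)
    avg = collapsed.mean(axis=0)  # (hemis, times)
    z = baseline_zscore(avg, epochs.times_s)
    return window_scores(z, epochs.times_s)


def evoked_summary(cohort: Cohort, align_polarity: bool = True) -> pd.DataFrame:
    """Evoked window scores for every participant and condition."""
    rows = []
    for ep in cohort.iter_epoch_sets():
        scores = evoked_epoch_scores(ep, align_polarity)
        rows.append(
            {
                "participant_id": ep.participant_id,
                "group": ep.group,
                "condition_N": ep.condition_n,
                **scores,
            }
        )
    return pd.DataFrame(rows)
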