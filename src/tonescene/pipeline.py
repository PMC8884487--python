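"""End-to-end pipeline: simulate -> analyze -> stats (optionally synth/validate).

Each run writes its artifacts plus a manifest of SHA-256 hashes; rerunning
the same config reproduces every stochastic output bit-identically.
"""

from __future__ import annotations

import hashlib
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .envelope import EnvelopeParams
from .erb import place_tones
from .evoked import evoked_summary
from .induced import TaperPlan, induced_summary
from .neuro import CohortSpec, ResponseModelParams, simulate_cohort
from .periphery import validate_trial
from .stats import (
    GroupConditionModel,
    classify_diagnosis,
    per_condition_contrast,
    predict_behavior,
    residualize_age,
)
from .stimulus import CoherenceSchedule, make_session, make_trial, write_event_log

log = logging.getLogger("tonescene")

__all__ = ["run_pipeline", "build_cohort_table", "StageError"]


class StageError(RuntimeError):
    """Failure inside one pipeline stage, tagged with the stage name."""

    def __init__(self, stage: str, err: Exception):
        super().__init__(f"[{stage}] {err}")
        self.stage = stage


def build_cohort_table(
    participants: pd.DataFrame,
    evoked: pd.DataFrame,
    induced: pd.DataFrame,
) -> pd.DataFrame:
    """Join neural summaries with the phenotype table.

    One row per participant x condition, carrying the evoked window
    z-scores, the gamma log-ratio and the behavioural scores.
    """
    tab = evoked.merge(
        induced[["participant_id", "condition_N", "gamma_logratio"]],
        on=["participant_id", "condition_N"],
    )
    return tab.merge(
        participants.drop(columns=["seed"], errors="ignore"),
        on=["participant_id", "group"],
    )


def _write(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return path


def run_pipeline(
    config: RunConfig,
    include_stimulus: bool = False,
    exclude: tuple[str, ...] = (),
) -> Path:
    """Execute the configured pipeline and return the run directory.

    ``include_stimulus`` additionally synthesises a small stimulus sample
    and runs the periphery audit (the neural stages start from simulated
    ROI epochs and do not need audio).  ``exclude`` drops participants by
    id before the statistics stage (sensitivity re-checks).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if include_stimulus:
        try:
            written += _stage_stimulus(config, out)
        except Exception as err:  # noqa: BLE001
            raise StageError("stimulus", err) from err

    try:
        stage = "simulate"
        log.info("simulating cohort")
        c = config["cohort"]
        spec = CohortSpec(
            n_td=int(c["n_td"]),
            n_asd=int(c["n_asd"]),
            trials_per_condition=int(c["trials_per_condition"]),
            sample_rate_hz=float(c["sample_rate_hz"]),
            epoch_window_s=tuple(c["epoch_window_s"]),
            master_seed=config.stage_seed("simulate"),
        )
        cohort = simulate_cohort(spec, ResponseModelParams())
        participants = cohort.participants
        written.append(_write(participants, out / "participants.tsv"))

        stage = "analyze"
        log.info("computing evoked and induced summaries")
        a = config["analysis"]
        plan = TaperPlan(
            window_s=float(a["window_s"]), nw=float(a["nw"]), n_tapers=int(a["n_tapers"])
        )
        ev = evoked_summary(cohort)
        ind = induced_summary(cohort, plan)
        table = build_cohort_table(participants, ev, ind)
        written.append(_write(table, out / "cohort_table.tsv"))

        stage = "stats"
        log.info("fitting group statistics")
        written += _stage_stats(config, table, out, exclude)
    except StageError:
        raise
    except Exception as err:  # noqa: BLE001
        raise StageError(stage, err) from err

    manifest = _manifest(config, written)
    manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    return out


def _stage_stimulus(config: RunConfig, out: Path) -> list[Path]:
    s = config["stimulus"]
    bank = place_tones(
        int(s["n_tones"]), float(s["f_lo_hz"]), float(s["f_hi_hz"]),
        float(s["per_tone_level_db"]),
    )
    env = EnvelopeParams(band_lo_hz=float(s["band_lo_hz"]), band_hi_hz=float(s["band_hi_hz"]))
    log_ = make_session(
        bank, env,
        conditions=tuple(s["conditions"]),
        trials_per_condition=int(s["trials_per_condition"]),
        isi_lo_s=float(s["isi_lo_s"]),
        isi_hi_s=float(s["isi_hi_s"]),
        seed=config.stage_seed("synth"),
    )
    paths = [write_event_log(log_, out / "session_log.tsv")]
    p = config["periphery"]
    rows = []
    rng = np.random.default_rng(config.stage_seed("validate"))
    for k in range(int(p["n_validate_trials"])):
        sched = CoherenceSchedule.random_subset(18, bank.n_tones, rng)
        stim = make_trial(bank, env, sched, rng=rng, audio_rate_hz=24000.0)
        rep = validate_trial(stim)
        rows.append(
            {
                "trial": k,
                "mean_rms_ratio": float(np.mean(rep.rms_ratio_per_channel)),
                "coherent_pair_r": rep.corr_coherent_pairs,
                "other_pair_abs_r": rep.corr_incoherent_pairs,
                "passed": rep.passed,
            }
        )
    paths.append(_write(pd.DataFrame(rows), out / "validation.tsv"))
    return paths


def _stage_stats(
    config: RunConfig, table: pd.DataFrame, out: Path, exclude: tuple[str, ...]
) -> list[Path]:
    if exclude:
        table = table[~table["participant_id"].isin(exclude)]
    st = config["stats"]
    paths = []
    report = []

    frames = []
    for measure in ("combined_z", "gamma_logratio"):
        res = GroupConditionModel(table, measure).fit()
        report.append(res.summary())
        frames.append(res.to_frame().assign(measure=measure))
        for n in sorted(table["condition_N"].unique()):
            t, p, df = per_condition_contrast(table, n, measure)
            report.append(f"  {measure} at N={n}: t({df}) = {t:.3f}, p = {p:.4g}")
    paths.append(_write(pd.concat(frames), out / "group_stats.tsv"))

    n18 = table[table["condition_N"] == 18].set_index("participant_id")
    clf = classify_diagnosis(
        n18[["combined_z", "gamma_logratio"]],
        n18["group"],
        test_fraction=float(st["test_fraction"]),
        n_repeats=int(st["n_repeats"]),
        seed=config.stage_seed("stats"),
        C=float(st["svm_c"]),
    )
    report.append(clf.summary())
    paths.append(
        _write(
            pd.DataFrame({"split": np.arange(clf.n_repeats), "accuracy_pct": clf.accuracies_pct}),
            out / "classifier.tsv",
        )
    )

    asd = n18[n18["group"] == "ASD"].copy()
    asd["spq_aps_ac"] = residualize_age(asd["spq_aps"].values, asd["age_years"].values)
    beh_rows = []
    jobs = [
        ("srs_sci", ("combined_z", "gamma_logratio"), ""),
        ("spq_aps_ac", ("combined_z", "gamma_logratio"), ""),
        # attention-confound control: ICSS-I should not track the evoked measure
        ("icss_i", ("combined_z",), "   [attention-confound control]"),
    ]
    for outcome, feats, tag in jobs:
        try:
            pred = predict_behavior(asd, outcome, feats)
        except ValueError as err:
            report.append(f"predicting {outcome}: skipped ({err})")
            continue
        report.append(pred.summary() + tag)
        beh_rows.append({"outcome": outcome, "r": pred.r, "p": pred.p})
    paths.append(_write(pd.DataFrame(beh_rows), out / "behavior.tsv"))
    report.append("note: p-values are unadjusted (planned contrasts)")

    (out / "report.txt").write_text("\n\n".join(report) + "\n")
    paths.append(out / "report.txt")
    return paths


def _manifest(config: RunConfig, paths: list[Path]) -> pd.DataFrame:
    rows = [
        {"key": "tonescene_version", "value": __version__},
        {"key": "master_seed", "value": str(config.master_seed)},
        {"key": "desk_scale", "value": str(config.desk_scale)},
    ]
    for p in sorted(set(paths)):
        digest = hashlib.sha256(Path(p).read_bytes()).hexdigest()
        rows.append({"key": f"sha256:{Path(p).name}", "value": digest})
    return pd.DataFrame(rows)
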