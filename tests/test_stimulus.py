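"""Trial and session synthesis: coherence structure, logs, file round-trips."""

import numpy as np
import pandas as pd
import pytest

from tests.conftest import TEST_AUDIO_RATE
from tonescene.envelope import EnvelopeParams
from tonescene.erb import place_tones
from tonescene.stimulus import (
    CoherenceSchedule,
    SeparationVariantSpec,
    make_separation_variant,
    make_session,
    make_trial,
    read_event_log,
    read_wav,
    realized_separation_erb,
    synthesize_logged_trial,
    variant_indices,
    write_event_log,
    write_wav,
)


def _env_segments(stim):
    """Per-segment envelope blocks, excluding crossfade zones."""
    fs = stim.envelope_rate_hz
    xf = int(round(0.010 * fs))
    bounds = np.round(stim.schedule.boundaries_s * fs).astype(int)
    out = []
    for s in range(stim.schedule.n_segments):
        hi = bounds[s + 1] - (xf if s + 1 < stim.schedule.n_segments else 0)
        out.append(stim.per_tone_envelopes[:, bounds[s] : hi])
    return out


class TestMakeTrial:
    def test_duration_exactly_4s(self, trial_n18):
        assert trial_n18.waveform.size == int(4.0 * trial_n18.sample_rate_hz)
        assert trial_n18.duration_s == 4.0

    def test_two_coherent_periods_at_1_and_3s(self, trial_n18):
        np.testing.assert_allclose(trial_n18.event_times_s, [1.0, 3.0])
        assert len(trial_n18.schedule.coherent_segments) == 2

    def test_envelopes_nonnegative(self, trial_n18):
        assert trial_n18.per_tone_envelopes.min() >= 0.0

    def test_coherent_subset_sample_identical(self, trial_n18):
        idx = trial_n18.schedule.coherent_tone_indices
        segs = _env_segments(trial_n18)
        for s in trial_n18.schedule.coherent_segments:
            block = segs[s][idx]
            np.testing.assert_array_equal(block, np.broadcast_to(block[0], block.shape))

    def test_incoherent_segments_have_no_identical_pair(self, trial_n18):
        segs = _env_segments(trial_n18)
        for s in (0, 2):
            block = segs[s]
            for i in range(block.shape[0]):
                for j in range(i + 1, block.shape[0]):
                    assert not np.array_equal(block[i], block[j])

    def test_full_coherence_all_identical(self, bank, env_params):
        sched = CoherenceSchedule(np.arange(20))
        stim = make_trial(bank, env_params, sched, seed=9, audio_rate_hz=TEST_AUDIO_RATE)
        segs = _env_segments(stim)
        for s in (1, 3):
            block = segs[s]
            np.testing.assert_array_equal(block, np.broadcast_to(block[0], block.shape))

    def test_zero_coherence_trial(self, bank, env_params):
        sched = CoherenceSchedule(np.array([], dtype=int))
        stim = make_trial(bank, env_params, sched, seed=9, audio_rate_hz=TEST_AUDIO_RATE)
        segs = _env_segments(stim)
        block = segs[1]
        for i in range(block.shape[0]):
            for j in range(i + 1, block.shape[0]):
                assert not np.array_equal(block[i], block[j])

    def test_oversized_subset_rejected(self, bank, env_params):
        small = place_tones(5, 200.0, 8000.0)
        sched = CoherenceSchedule(np.arange(6))
        with pytest.raises(ValueError):
            make_trial(small, env_params, sched, audio_rate_hz=TEST_AUDIO_RATE)

    def test_envelope_stationarity(self, bank, env_params):
        """Within-channel modulation RMS is the same in coherent and
        incoherent periods, per trial and on average."""
        ratios = []
        for seed in range(30):
            sched = CoherenceSchedule.random_subset(
                12, 20, np.random.default_rng(1000 + seed)
            )
            stim = make_trial(
                bank, env_params, sched, seed=1000 + seed, audio_rate_hz=TEST_AUDIO_RATE
            )
            segs = _env_segments(stim)
            rms = lambda b: np.sqrt(np.mean(b**2, axis=1))
            coh = np.sqrt((rms(segs[1]) ** 2 + rms(segs[3]) ** 2) / 2)
            inc = np.sqrt((rms(segs[0]) ** 2 + rms(segs[2]) ** 2) / 2)
            r = coh / inc
            assert np.all(r > 0.8) and np.all(r < 1.25)
            ratios.append(r.mean())
        assert 0.97 < np.mean(ratios) < 1.03


class TestSession:
    def test_default_counts_and_isi(self, bank, env_params):
        log = make_session(bank, env_params, seed=1)
        counts = log.counts_per_condition()
        assert dict(counts) == {6: 240, 12: 240, 18: 240}
        assert log.records["isi_s"].between(1.2, 1.3).all()

    def test_single_trial_session(self, bank, env_params):
        log = make_session(bank, env_params, conditions=(18,), trials_per_condition=1, seed=2)
        assert len(log) == 1

    def test_bad_isi_rejected(self, bank, env_params):
        with pytest.raises(ValueError):
            make_session(bank, env_params, isi_lo_s=1.3, isi_hi_s=1.2, seed=0)

    def test_session_reproducible(self, bank, env_params):
        a = make_session(bank, env_params, trials_per_condition=5, seed=3)
        b = make_session(bank, env_params, trials_per_condition=5, seed=3)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_trial_resynthesis_bit_identical(self, bank, env_params):
        log = make_session(bank, env_params, trials_per_condition=2, seed=4)
        row = log.records.iloc[3]
        s1 = synthesize_logged_trial(row, bank, env_params, TEST_AUDIO_RATE)
        s2 = synthesize_logged_trial(row, bank, env_params, TEST_AUDIO_RATE)
        np.testing.assert_array_equal(s1.waveform, s2.waveform)
        assert int(row["condition_N"]) == s1.schedule.n_coherent


class TestSeparationVariants:
    def test_narrow_contiguous_spacing(self, bank):
        idx = variant_indices(SeparationVariantSpec(6, "narrow"), 20)
        assert list(np.diff(idx)) == [1] * 5
        assert realized_separation_erb(idx, bank) == pytest.approx(1.445, abs=0.001)

    def test_wide_stride_separation(self, bank):
        # stride 4 is feasible for 5 coherent tones on the 20-tone grid
        idx = variant_indices(SeparationVariantSpec(5, "wide", stride=4), 20)
        assert list(np.diff(idx)) == [4] * 4
        assert realized_separation_erb(idx, bank) == pytest.approx(5.78, abs=0.01)

    def test_wide_default_max_stride(self, bank):
        idx = variant_indices(SeparationVariantSpec(4, "wide"), 20)
        assert list(np.diff(idx)) == [6] * 3

    def test_infeasible_spread_rejected(self):
        with pytest.raises(ValueError):
            variant_indices(SeparationVariantSpec(6, "wide", stride=4), 20)

    def test_matched_broadband_envelope_rms(self, bank, env_params):
        """Same coherent-tone count => same summed-envelope amplitude
        statistics during the coherent periods, narrow or wide."""
        def coherent_rms(mode, seed):
            stim = make_separation_variant(
                SeparationVariantSpec(6, mode), bank, env_params, seed=seed,
                audio_rate_hz=TEST_AUDIO_RATE,
            )
            e = stim.per_tone_envelopes.sum(axis=0)
            fs = stim.envelope_rate_hz
            seg = np.concatenate([
                e[int(1.0 * fs): int(1.99 * fs)], e[int(3.0 * fs): int(3.99 * fs)]
            ])
            return np.sqrt(np.mean(seg**2))

        narrow = np.mean([coherent_rms("narrow", s) for s in range(20)])
        wide = np.mean([coherent_rms("wide", 100 + s) for s in range(20)])
        assert abs(narrow - wide) / narrow < 0.02


class TestFileIO:
    def test_wav_round_trip(self, trial_n18, tmp_path):
        p = write_wav(trial_n18, tmp_path / "t.wav")
        data, rate = read_wav(p)
        assert rate == trial_n18.sample_rate_hz
        np.testing.assert_array_equal(data, trial_n18.waveform.astype(np.float32))

    def test_event_log_round_trip(self, bank, env_params, tmp_path):
        log = make_session(bank, env_params, trials_per_condition=3, seed=6)
        p = write_event_log(log, tmp_path / "log.tsv")
        back = read_event_log(p)
        assert len(back) == len(log)
        pd.testing.assert_frame_equal(back.records, log.records)
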