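"""Synthetic corpus generators: lexicon, discourse, covariates, recording."""

import numpy as np
import pytest

from neurolex import features, synth
from neurolex.features import log_transform
from neurolex.synth import (
    CORPUS_SIZE,
    DiscourseConfig,
    EffectSpec,
    generate_discourse,
    generate_lexicon,
    synthesize_covariates,
    synthesize_recording,
    token_parameter_values,
)
from neurolex.timeline import PAUSE_THRESHOLD


class TestLexicon:
    def test_single_word_gets_the_normalization_constant(self):
        lex = generate_lexicon(1, seed=0)
        (freq,) = lex.frequencies.values()
        assert freq == CORPUS_SIZE

    def test_zipf_law_rank_ratio(self):
        lex = generate_lexicon(1000, zipf_exponent=1.0, seed=7)
        freqs = sorted(lex.frequencies.values(), reverse=True)
        assert freqs[0] / freqs[1] == pytest.approx(2.0)

    def test_frequency_couples_negatively_to_syllable_count(self):
        lex = generate_lexicon(500, seed=11)
        nos = np.array([features.count_syllables(w) for w in lex.entries], float)
        logf = np.log([lex.frequency_of(w) for w in lex.entries])
        r = np.corrcoef(logf, nos)[0, 1]
        assert r < 0 and abs(r) > 0.3

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            generate_lexicon(0)
        with pytest.raises(ValueError):
            generate_lexicon(10, zipf_exponent=0.0)

    def test_lemma_pos_pairs_unique(self, small_lexicon):
        pairs = [(w.lemma, w.pos) for w in small_lexicon.entries]
        assert len(set(pairs)) == len(pairs)

    def test_deterministic_under_seed(self):
        a = generate_lexicon(50, seed=5).to_frame()
        b = generate_lexicon(50, seed=5).to_frame()
        assert a.equals(b)


class TestDiscourse:
    def test_epoch_gap_invariants(self, small_discourse):
        toks = small_discourse.tokens
        for prev, cur in zip(toks, toks[1:]):
            gap = cur.onset - prev.offset
            if cur.epoch_id == prev.epoch_id:
                assert gap < PAUSE_THRESHOLD
            else:
                assert gap >= PAUSE_THRESHOLD

    def test_epoch_count_matches_pause_rule(self, small_discourse):
        toks = small_discourse.tokens
        pauses = sum(
            cur.onset - prev.offset >= PAUSE_THRESHOLD
            for prev, cur in zip(toks, toks[1:])
        )
        assert len(small_discourse.epochs) == pauses + 1

    def test_longer_words_occur_later_in_their_epoch(self, small_lexicon):
        disc = generate_discourse(small_lexicon, DiscourseConfig(seed=3))
        ss_ws = np.array([t.onset - disc.epoch_of(t)[0] for t in disc.tokens])
        nos = token_parameter_values(disc, "NoS")
        frq = token_parameter_values(disc, "FRQ")
        assert np.corrcoef(ss_ws, nos)[0, 1] > 0
        assert np.corrcoef(ss_ws, np.log(frq))[0, 1] < 0

    def test_empty_lexicon_rejected(self, small_lexicon):
        with pytest.raises(ValueError):
            generate_discourse(
                small_lexicon, DiscourseConfig(n_tokens={"FV": 10**6})
            )

    def test_pause_config_must_straddle_threshold(self):
        with pytest.raises(ValueError):
            DiscourseConfig(gap_range=(0.1, 0.3))
        with pytest.raises(ValueError):
            DiscourseConfig(pause_range=(0.1, 0.15))

    def test_deterministic_under_seed(self, small_lexicon):
        cfg = DiscourseConfig(seed=9, n_tokens={"FV": 20, "NN": 15, "ADV": 15})
        a = generate_discourse(small_lexicon, cfg)
        b = generate_discourse(small_lexicon, cfg)
        assert [(t.token_id, t.onset, t.offset) for t in a.tokens] == [
            (t.token_id, t.onset, t.offset) for t in b.tokens
        ]


class TestCovariates:
    def test_one_row_per_token(self, small_discourse):
        cov = synthesize_covariates(small_discourse, seed=5)
        assert len(cov.table) == len(small_discourse.tokens)

    def test_intensity_is_finite_db(self, small_discourse):
        cov = synthesize_covariates(small_discourse, seed=5)
        vals = cov.table["intensity_db"]
        assert np.isfinite(vals).all() and (vals > 0).all()

    def test_intensity_declines_over_the_epoch(self, small_discourse):
        cov = synthesize_covariates(small_discourse, seed=5)
        ss_ws = np.array(
            [t.onset - small_discourse.epoch_of(t)[0] for t in small_discourse.tokens]
        )
        assert np.corrcoef(cov.table["intensity_db"], ss_ws)[0, 1] < 0


class TestRecording:
    def test_deterministic_bit_identical(self, small_discourse):
        eff = [EffectSpec(channel=1, parameter="NoS", r=0.4)]
        a = synthesize_recording(small_discourse, eff, n_channels=3, seed=4)
        b = synthesize_recording(small_discourse, eff, n_channels=3, seed=4)
        assert np.array_equal(a.data, b.data)

    def test_no_effects_no_word_locked_coupling(self, small_discourse):
        rec = synthesize_recording(small_discourse, [], n_channels=2, seed=6)
        onsets = small_discourse.onsets()
        nos = log_transform(token_parameter_values(small_discourse, "NoS"))
        L = synth._band_window_logrsm(
            rec.data[0], rec.fs, onsets, (70.0, 110.0), (0.0, 0.4)
        )
        assert abs(np.corrcoef(L, nos)[0, 1]) < 0.25

    def test_injected_coupling_near_target(self, small_discourse):
        """Realized band-averaged coupling within the n=140 sampling band."""
        eff = EffectSpec(channel=0, parameter="CVR", r=0.5)
        rec = synthesize_recording(small_discourse, [eff], n_channels=2, seed=21)
        onsets = small_discourse.onsets()
        cvr = log_transform(token_parameter_values(small_discourse, "CVR"))
        L = synth._band_window_logrsm(
            rec.data[0], rec.fs, onsets, eff.band, eff.probe_window
        )
        assert np.corrcoef(L, cvr)[0, 1] == pytest.approx(0.5, abs=0.15)

    def test_negative_sign_flips_the_coupling(self, small_discourse):
        eff = EffectSpec(channel=0, parameter="NoS", r=0.5, sign=-1)
        rec = synthesize_recording(small_discourse, [eff], n_channels=1, seed=8)
        onsets = small_discourse.onsets()
        nos = log_transform(token_parameter_values(small_discourse, "NoS"))
        L = synth._band_window_logrsm(
            rec.data[0], rec.fs, onsets, eff.band, eff.probe_window
        )
        assert np.corrcoef(L, nos)[0, 1] < -0.2

    def test_band_above_nyquist_rejected(self, small_discourse):
        with pytest.raises(ValueError):
            synthesize_recording(
                small_discourse,
                [EffectSpec(channel=0, parameter="NoS", band=(400.0, 500.0))],
                fs=256.0,
            )

    def test_effect_channel_must_exist(self, small_discourse):
        with pytest.raises(ValueError):
            synthesize_recording(
                small_discourse,
                [EffectSpec(channel=7, parameter="NoS")],
                n_channels=4,
            )


def test_effect_spec_invariants():
    with pytest.raises(ValueError):
        EffectSpec(channel=0, parameter="NoS", r=1.5)
    with pytest.raises(ValueError):
        EffectSpec(channel=0, parameter="NoS", band=(0.0, 100.0))
    with pytest.raises(ValueError):
        EffectSpec(channel=0, parameter="NoS", window=(-3.0, 0.0))
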