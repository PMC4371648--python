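"""Training protocols: trial bookkeeping, error scaling, phase behavior.

Heavy simulations live in the acceptance tests; here a 10-word fixture
corpus keeps every run to a few seconds.
"""

import numpy as np
import pytest

from dialectnet.network import init_network
from dialectnet.rules import build_aae_corpus
from dialectnet.synth import GenSpec, generate_lexicon
from dialectnet.training import (
    CONDITIONS, CorpusPatterns, READING_ERROR_RATIO, TrainingCondition,
    _reading_epoch_arrays, _speech_epoch_arrays, desk_config, run_condition,
    run_condition_suite, run_reading_phase, run_speech_phase,
)


@pytest.fixture(scope="module")
def small_patterns():
    lex = generate_lexicon(GenSpec(n_words=10, target_rule_fraction=0.5, seed=5))
    return CorpusPatterns(build_aae_corpus(lex, seed=5))


@pytest.fixture
def small_net(small_patterns):
    cfg = desk_config(small_patterns.corpus, seed=0, learning_rate=0.1)
    return init_network(cfg)


class TestConditionDefinitions:
    def test_bidialectal_conditions_read_mae(self):
        for cond in CONDITIONS.values():
            if cond.bidialectal or cond.name == "mismatch":
                assert cond.reading_targets == "mae"

    def test_invalid_condition_combinations_rejected(self):
        with pytest.raises(ValueError):
            TrainingCondition("bad", "both", "aae", "never")
        with pytest.raises(ValueError):
            TrainingCondition("bad2", "mae", "mae", "sometimes")

    def test_late_schedule_activates_at_half(self):
        late = CONDITIONS["bidialectal_late"]
        assert not late.context_active(99, 200)
        assert late.context_active(100, 200)


class TestTrialBookkeeping:
    def test_each_word_once_per_trial_type_per_epoch(self, small_patterns):
        rng = np.random.default_rng(0)
        for name in ("mae_match", "mismatch", "bidialectal_early"):
            out = _reading_epoch_arrays(small_patterns, CONDITIONS[name], rng, 0, 10)
            orth, has_orth, clamp, has_clamp, ctx, tgt, scales, word_index = out
            n = small_patterns.n_words
            assert np.bincount(word_index[has_orth], minlength=n).tolist() == [1] * n
            assert np.bincount(word_index[has_clamp], minlength=n).tolist() == [1] * n

    def test_reading_to_speech_error_ratio_is_one_tenth(self, small_patterns):
        rng = np.random.default_rng(0)
        cond = CONDITIONS["mae_match"]
        _, has_orth, _, _, _, _, scales, word_index = _reading_epoch_arrays(
            small_patterns, cond, rng, 0, 10)
        n = small_patterns.n_words
        reading = scales[:n][np.argsort(word_index[:n])]
        speech = scales[n:][np.argsort(word_index[n:])]
        np.testing.assert_allclose(reading / speech, READING_ERROR_RATIO)

    def test_bidialectal_split_sums_to_twice_root_half_frequency(self, small_patterns):
        # the two speech variants of a Contrastive word each carry
        # sqrt(f/2); their sum is 2*sqrt(f/2) on the normalised scale
        half = small_patterns.speech_scale_half["sqrt_half"]
        freq = np.array([w.frequency for w in small_patterns.corpus])
        z = np.sqrt(freq).mean()
        np.testing.assert_allclose(half + half, 2 * np.sqrt(freq / 2) / z)

    def test_speech_targets_follow_condition_dialect(self, small_patterns):
        rng = np.random.default_rng(0)
        clamp, tgt, scales, ctx = _speech_epoch_arrays(
            small_patterns, CONDITIONS["mismatch"], rng)
        np.testing.assert_array_equal(tgt, small_patterns.phon_aae)
        np.testing.assert_array_equal(clamp, tgt)
        np.testing.assert_allclose(scales, small_patterns.speech_scale)

    def test_bidialectal_input_is_always_the_aae_form(self, small_patterns):
        # the clamp never reveals the target dialect: producing the MAE
        # variant from AAE input is a conversion, not maintenance
        rng = np.random.default_rng(3)
        clamp, tgt, _, _ = _speech_epoch_arrays(
            small_patterns, CONDITIONS["bidialectal_none"], rng)
        np.testing.assert_array_equal(clamp, small_patterns.phon_aae)
        is_mae = np.all(tgt == small_patterns.phon_mae, axis=1)
        is_aae = np.all(tgt == small_patterns.phon_aae, axis=1)
        assert np.all(is_mae | is_aae)

    def test_bidialectal_context_units_mark_presented_dialect(self, small_patterns):
        rng = np.random.default_rng(3)
        cond = CONDITIONS["bidialectal_early"]
        clamp, tgt, scales, ctx = _speech_epoch_arrays(
            small_patterns, cond, rng, context_active=True)
        con = small_patterns.contrastive
        # non-contrastive words always light the MAE unit
        assert np.all(ctx[~con, 1] == 1.0) and np.all(ctx[~con, 0] == 0.0)
        # contrastive: MAE unit iff the MAE variant is the target
        is_mae = np.all(tgt == small_patterns.phon_mae, axis=1)
        np.testing.assert_array_equal(ctx[con, 1] == 1.0, is_mae[con])
        # contrastive scales are the half-frequency ones
        np.testing.assert_allclose(scales[con], small_patterns.speech_scale_half["sqrt_half"][con])


class TestSpeechPhase:
    def test_reaches_criterion_on_small_corpus(self, small_net, small_patterns):
        net, report = run_speech_phase(
            small_net, small_patterns, CONDITIONS["mae_match"],
            criterion=95.0, seed=0, max_epochs=600)
        assert report.reached_criterion
        assert report.final["speech_accuracy"] >= 95.0

    def test_single_word_reaches_full_criterion(self):
        lex = generate_lexicon(GenSpec(n_words=10, seed=5))
        one = build_aae_corpus(lex, seed=5)
        one.words = one.words[:1]
        patterns = CorpusPatterns(one)
        net = init_network(desk_config(one, seed=0, learning_rate=0.1))
        _, report = run_speech_phase(net, patterns, CONDITIONS["mae_match"],
                                     criterion=100.0, seed=0, max_epochs=600)
        assert report.reached_criterion

    def test_epoch_cap_respected_without_failure(self, small_net, small_patterns):
        _, report = run_speech_phase(
            small_net, small_patterns, CONDITIONS["bidialectal_none"],
            criterion=95.0, seed=0, epoch_cap=5)
        assert report.termination_epoch == 5
        assert report.reached_criterion is False

    def test_invalid_criterion_rejected(self, small_net, small_patterns):
        with pytest.raises(ValueError):
            run_speech_phase(small_net, small_patterns, CONDITIONS["mae_match"],
                             criterion=0.0)


class TestReadingPhase:
    def test_rejects_nonpositive_epochs(self, small_net, small_patterns):
        with pytest.raises(ValueError):
            run_reading_phase(small_net, small_patterns, CONDITIONS["mae_match"], epochs=0)

    def test_run_is_reproducible_from_seed(self, small_patterns):
        def one_run():
            res = run_condition(small_patterns, "mismatch", seed=4,
                                config=desk_config(small_patterns.corpus, 4, 0.1),
                                reading_epochs=30, eval_every=10)
            return res["reading_report"].frame(), res["network"]

        frame_a, net_a = one_run()
        frame_b, net_b = one_run()
        assert frame_a.equals(frame_b)
        for name in net_a.weights():
            np.testing.assert_array_equal(getattr(net_a, name), getattr(net_b, name))


class TestSuite:
    def test_suite_bookkeeping_and_epoch_matching(self, small_patterns):
        results = run_condition_suite(
            small_patterns, ["mismatch", "bidialectal_none"], seeds=[0, 1],
            config=desk_config(small_patterns.corpus, 0, 0.1),
            reading_epochs=10, eval_every=5)
        assert len(results) == 4
        by = {(r["condition"], r["seed"]): r for r in results}
        for seed in (0, 1):
            cap = by[("mismatch", seed)]["speech_report"].termination_epoch
            bid = by[("bidialectal_none", seed)]["speech_report"].termination_epoch
            assert bid <= cap  # bi-dialectal speech matched to the AAE phase

    def test_duplicate_seeds_rejected(self, small_patterns):
        with pytest.raises(ValueError):
            run_condition_suite(small_patterns, ["mae_match"], seeds=[0, 0])


def test_bidialectal_speech_lags_match_at_matched_epochs(small_patterns):
    """With speech epochs matched to the single-dialect phase, the
    bi-dialectal learner reproduces fewer items: Contrastive words have
    two targets for one input, so it cannot satisfy both without cues."""
    from dialectnet.training import speech_eval_accuracy

    cfg = desk_config(small_patterns.corpus, seed=0, learning_rate=0.1)
    net = init_network(cfg)
    net, match_rep = run_speech_phase(net, small_patterns, CONDITIONS["aae_match"],
                                      criterion=95.0, seed=0, max_epochs=800)
    cap = match_rep.termination_epoch

    bid_net = init_network(cfg)
    bid_cond = CONDITIONS["bidialectal_none"]
    bid_net, bid_rep = run_speech_phase(bid_net, small_patterns, bid_cond,
                                        criterion=95.0, seed=0, epoch_cap=cap)
    assert bid_rep.final["speech_accuracy"] < match_rep.final["speech_accuracy"]
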