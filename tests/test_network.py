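"""Attractor-net core: settling, loss, BPTT gradients, learning."""

import numpy as np
import pytest

from dialectnet.network import (
    NetConfig, TrialSpec, init_network, settle, train_trial, trial_gradients,
    trial_loss,
)


def finite_difference_gradients(net, trial, eps=1e-6):
    """Independent oracle: central differences of the trial loss."""
    out = {}
    for name, w in net.weights().items():
        g = np.zeros_like(w)
        for idx in np.ndindex(w.shape):
            if name == "W_pp" and idx[0] == idx[1]:
                continue  # diagonal is structurally zero
            orig = w[idx]
            w[idx] = orig + eps
            lp = trial_loss(settle(net, trial), trial)
            w[idx] = orig - eps
            lm = trial_loss(settle(net, trial), trial)
            w[idx] = orig
            g[idx] = (lp - lm) / (2 * eps)
        out[name] = g
    return out


def _random_trial(cfg, rng, kind="reading", scale=1.3):
    tgt = (rng.random(cfg.n_phon) < 0.4).astype(float)
    ctx = np.array([1.0, 0.0])
    if kind == "reading":
        orth = (rng.random(cfg.n_orth) < 0.5).astype(float)
        return TrialSpec(target=tgt, orth_input=orth, context=ctx, error_scale=scale)
    return TrialSpec(target=tgt, phon_clamp=tgt, context=ctx, error_scale=scale)


class TestInit:
    def test_same_seed_identical_weights(self, tiny_config):
        a, b = init_network(tiny_config), init_network(tiny_config)
        for name in a.weights():
            np.testing.assert_array_equal(getattr(a, name), getattr(b, name))

    def test_different_seeds_differ(self, tiny_config):
        from dataclasses import replace
        a = init_network(tiny_config)
        b = init_network(replace(tiny_config, seed=tiny_config.seed + 1))
        assert not np.allclose(a.W_pp, b.W_pp)

    def test_zero_init_range_settles_at_half(self, tiny_config):
        from dataclasses import replace
        cfg = replace(tiny_config, init_range=0.0, bias_init=0.0)
        net = init_network(cfg)
        trial = TrialSpec(target=np.zeros(cfg.n_phon), orth_input=np.ones(cfg.n_orth))
        traj = settle(net, trial)
        np.testing.assert_allclose(traj.phon[1:], 0.5)

    def test_phon_recurrence_has_zero_diagonal(self, tiny_net):
        assert np.all(np.diag(tiny_net.W_pp) == 0.0)


class TestSettle:
    def test_clamped_steps_hold_the_clamp_pattern(self, tiny_net, rng):
        cfg = tiny_net.config
        trial = _random_trial(cfg, rng, kind="speech")
        traj = settle(tiny_net, trial)
        for t in range(cfg.clamp_steps + 1):
            np.testing.assert_array_equal(traj.phon[t], trial.target)

    def test_inputs_held_constant_hidden_is_static(self, tiny_net, rng):
        traj = settle(tiny_net, _random_trial(tiny_net.config, rng))
        assert traj.hidden.shape == (tiny_net.config.n_hidden,)

    def test_trained_toy_net_reaches_fixed_point(self, tiny_config, rng):
        net = init_network(tiny_config)
        trial = _random_trial(tiny_config, rng, kind="speech", scale=1.0)
        for _ in range(300):
            train_trial(net, trial)
        traj = settle(net, trial)
        assert traj.max_step_change() < 1e-3


class TestTrialLoss:
    def test_perfect_output_gives_near_zero_loss(self, tiny_net, rng):
        cfg = tiny_net.config
        trial = _random_trial(cfg, rng, kind="speech")
        traj = settle(tiny_net, trial)
        traj.phon[-cfg.target_steps:] = trial.target
        assert trial_loss(traj, trial) < 1e-5

    def test_uniform_half_activation_closed_form(self, tiny_config, rng):
        from dataclasses import replace
        cfg = replace(tiny_config, init_range=0.0, bias_init=0.0)
        net = init_network(cfg)
        tgt = (rng.random(cfg.n_phon) < 0.5).astype(float)
        trial = TrialSpec(target=tgt, orth_input=np.ones(cfg.n_orth), error_scale=2.5)
        loss = trial_loss(settle(net, trial), trial)
        expected = 2.5 * cfg.target_steps * cfg.n_phon * np.log(2.0)
        assert loss == pytest.approx(expected, rel=1e-12)

    def test_matches_independent_double_loop(self, tiny_net, rng):
        cfg = tiny_net.config
        trial = _random_trial(cfg, rng)
        traj = settle(tiny_net, trial)
        acc = 0.0
        for t in range(cfg.settle_steps - cfg.target_steps + 1, cfg.settle_steps + 1):
            for j in range(cfg.n_phon):
                a = min(max(traj.phon[t, j], 1e-7), 1 - 1e-7)
                tj = trial.target[j]
                acc -= tj * np.log(a) + (1 - tj) * np.log(1 - a)
        assert trial_loss(traj, trial) == pytest.approx(acc * trial.error_scale, rel=1e-12)


class TestGradients:
    @pytest.mark.parametrize("kind", ["reading", "speech"])
    def test_bptt_matches_finite_differences(self, tiny_net, rng, kind):
        trial = _random_trial(tiny_net.config, rng, kind=kind)
        analytic, _ = trial_gradients(tiny_net, trial)
        numeric = finite_difference_gradients(tiny_net, trial)
        for name in analytic:
            denom = np.maximum(np.maximum(np.abs(numeric[name]), np.abs(analytic[name])), 1e-8)
            rel = np.abs(numeric[name] - analytic[name]) / denom
            assert rel.max() < 1e-4, f"{name}: max rel err {rel.max():.2e}"

    def test_zero_learning_rate_leaves_weights_unchanged(self, tiny_config, rng):
        from dataclasses import replace
        net = init_network(replace(tiny_config, learning_rate=0.0))
        before = {k: v.copy() for k, v in net.weights().items()}
        train_trial(net, _random_trial(net.config, rng))
        for name, w in net.weights().items():
            np.testing.assert_array_equal(w, before[name])

    def test_zero_diagonal_preserved_by_updates(self, tiny_net, rng):
        for _ in range(20):
            train_trial(tiny_net, _random_trial(tiny_net.config, rng))
        assert np.all(np.diag(tiny_net.W_pp) == 0.0)


class TestLearning:
    def test_repeated_trials_drive_loss_down(self, tiny_config, rng):
        net = init_network(tiny_config)
        trial = _random_trial(tiny_config, rng, kind="speech", scale=1.0)
        losses = [train_trial(net, trial)[1] for _ in range(500)]
        windows = [np.mean(losses[i:i + 100]) for i in range(0, 500, 100)]
        assert all(b < a for a, b in zip(windows, windows[1:]))

    def test_toy_mapping_task_reaches_full_decode_accuracy(self):
        """10 orthography->phonology patterns learned to the 0.75/0.25
        criterion within a bounded trial budget, deterministically."""
        from dialectnet.encoding import decode_phonology, encode_orthography, encode_phonology
        from dialectnet.lexicon import PhonemeInventory
        from dialectnet.synth import GenSpec, generate_lexicon

        lex = generate_lexicon(GenSpec(n_words=10, target_rule_fraction=0.5, seed=5))
        inv = lex.inventory
        cfg = NetConfig(
            n_orth=312, n_hidden=50, n_phon=10 * len(inv), n_cleanup=20,
            settle_steps=8, clamp_steps=4, target_steps=2,
            learning_rate=0.1, seed=3,
        )
        net = init_network(cfg)
        trials = [
            TrialSpec(target=encode_phonology(e.phonemes, inv),
                      orth_input=encode_orthography(e.spelling))
            for e in lex
        ]
        rng = np.random.default_rng(7)
        budget, accuracy = 0, 0.0
        for _ in range(400):  # epochs; well under a 10k-trial budget
            for i in rng.permutation(len(trials)):
                train_trial(net, trials[i])
                budget += 1
            decoded = [
                decode_phonology(settle(net, tr).final_phon, inv) for tr in trials
            ]
            accuracy = np.mean([d == e.phonemes for d, e in zip(decoded, lex)])
            if accuracy == 1.0:
                break
        assert accuracy == 1.0, f"stuck at {accuracy:.0%} after {budget} trials"
        assert budget <= 4000


class TestCheckpointing:
    def test_save_load_round_trip(self, tiny_net, tmp_path):
        from dialectnet.network import load_network, save_network
        path = tmp_path / "net.npz"
        save_network(tiny_net, path)
        back = load_network(path)
        assert back.config == tiny_net.config
        for name, w in tiny_net.weights().items():
            np.testing.assert_array_equal(getattr(back, name), w)
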