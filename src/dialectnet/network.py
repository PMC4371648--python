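"""The trainable attractor network.

Architecture: an orthographic input layer feeds a hidden layer, which
feeds a phonological output layer; the phonological units are fully
interconnected (no self-connections) and reciprocally connected to a
small bank of cleanup units, so the phonological side forms an attractor
network that settles toward learned pronunciations.  Two optional
context units (one per dialect) feed both the hidden and phonological
layers and can cue which dialect's pronunciation is wanted.

Settling is discrete-time and synchronous with logistic units.  On
speech trials the pronunciation pattern is clamped on the phonological
layer for the first ``clamp_steps`` steps and the network must maintain
it after the clamp is removed; on reading trials the orthographic
pattern is held on the input throughout.  Learning is online gradient
descent on cross-entropy error summed over the final ``target_steps``
steps, with gradients computed by backpropagation through the unrolled
settling steps (BPTT), one weight update per trial.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _kernels
from ._kernels import EPS

__all__ = ["NetConfig", "TrialSpec", "Trajectory", "Network", "init_network",
           "settle", "trial_loss", "train_trial", "trial_gradients", "run_trials",
           "save_network", "load_network"]


@dataclass(frozen=True)
class NetConfig:
    """Layer sizes, settling schedule, and learning hyperparameters.

    Defaults give the full-inventory layer sizes (orthography 312,
    hidden 50, phonology 390, cleanup 20, context 2).  The settling
    schedule and learning rate are this package's own defaults, tuned
    on the toy fixtures: 12 synchronous update steps, a 6-step clamp on
    speech trials, error scored over the last 3 steps.  `delta_clip`
    (0 disables) caps the joint norm of the BPTT deltas per trial, a
    stability guard for large frequency-scaled errors.
    """

    n_orth: int = 312
    n_hidden: int = 50
    n_phon: int = 390
    n_cleanup: int = 20
    n_context: int = 2
    settle_steps: int = 12
    clamp_steps: int = 6
    target_steps: int = 3
    learning_rate: float = 0.005
    error_margin: float = 0.0
    delta_clip: float = 0.0
    init_range: float = 0.1
    bias_init: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_orth", "n_hidden", "n_phon", "n_cleanup", "n_context"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.target_steps <= self.settle_steps):
            raise ValueError("need 0 < target_steps <= settle_steps")
        if not (0 <= self.clamp_steps < self.settle_steps):
            raise ValueError("need 0 <= clamp_steps < settle_steps")
        if self.clamp_steps + self.target_steps > self.settle_steps:
            raise ValueError("target window must not overlap the clamp")

    @property
    def a_init(self) -> float:
        """Resting activation of free units: logistic of the initial bias."""
        return float(1.0 / (1.0 + np.exp(-self.bias_init)))


@dataclass
class TrialSpec:
    """One training or test trial.

    Exactly the inputs present drive the network: reading trials supply
    ``orth_input``; speech (pattern-maintenance) trials supply
    ``phon_clamp``.  ``error_scale`` multiplies the cross-entropy error,
    carrying the word-frequency weighting.
    """

    target: np.ndarray
    orth_input: np.ndarray | None = None
    phon_clamp: np.ndarray | None = None
    context: np.ndarray | None = None
    error_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.orth_input is None and self.phon_clamp is None:
            raise ValueError("trial needs an orthographic input or a phonological clamp")
        if not (np.isfinite(self.error_scale) and self.error_scale >= 0):
            raise ValueError("error_scale must be finite and >= 0")


@dataclass
class Trajectory:
    """Per-step activations from one settling run."""

    phon: np.ndarray      # (settle_steps + 1, n_phon); row 0 is the initial state
    cleanup: np.ndarray   # (settle_steps + 1, n_cleanup)
    hidden: np.ndarray    # (n_hidden,) — constant across steps
    config: NetConfig

    @property
    def final_phon(self) -> np.ndarray:
        return self.phon[-1]

    def max_step_change(self) -> float:
        """Largest unit-wise change over the last free step (fixed-point check)."""
        return float(np.max(np.abs(self.phon[-1] - self.phon[-2])))


_WEIGHT_NAMES = ("W_oh", "W_ch", "b_h", "W_hp", "W_pp", "W_cp", "W_xp",
                 "b_p", "W_pc", "b_c")


@dataclass
class Network:
    """Weight blocks of the attractor net; mutated in place by training."""

    config: NetConfig
    W_oh: np.ndarray  # orthography -> hidden
    W_ch: np.ndarray  # context -> hidden
    b_h: np.ndarray
    W_hp: np.ndarray  # hidden -> phonology
    W_pp: np.ndarray  # phonology <-> phonology, zero diagonal
    W_cp: np.ndarray  # cleanup -> phonology
    W_xp: np.ndarray  # context -> phonology
    b_p: np.ndarray
    W_pc: np.ndarray  # phonology -> cleanup
    b_c: np.ndarray

    def weights(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in _WEIGHT_NAMES}

    def copy(self) -> "Network":
        return Network(self.config, *(getattr(self, n).copy() for n in _WEIGHT_NAMES))

    def check_finite(self) -> None:
        for name, w in self.weights().items():
            if not np.all(np.isfinite(w)):
                raise FloatingPointError(f"non-finite weights in {name}")


def init_network(config: NetConfig) -> Network:
    """Fresh network with uniform weights in [-init_range, init_range].

    Biases start at a small negative constant so free-running units rest
    near zero activation, matching the sparse localist targets.
    """
    rng = np.random.default_rng(config.seed)
    r = config.init_range

    def u(n_in: int, n_out: int) -> np.ndarray:
        return rng.uniform(-r, r, size=(n_in, n_out))

    net = Network(
        config=config,
        W_oh=u(config.n_orth, config.n_hidden),
        W_ch=u(config.n_context, config.n_hidden),
        b_h=np.full(config.n_hidden, config.bias_init),
        W_hp=u(config.n_hidden, config.n_phon),
        W_pp=u(config.n_phon, config.n_phon),
        W_cp=u(config.n_cleanup, config.n_phon),
        W_xp=u(config.n_context, config.n_phon),
        b_p=np.full(config.n_phon, config.bias_init),
        W_pc=u(config.n_phon, config.n_cleanup),
        b_c=np.full(config.n_cleanup, config.bias_init),
    )
    np.fill_diagonal(net.W_pp, 0.0)
    return net


def _trial_arrays(net: Network, trial: TrialSpec):
    cfg = net.config
    orth = np.zeros(cfg.n_orth) if trial.orth_input is None else np.asarray(trial.orth_input, dtype=float)
    clamp = np.zeros(cfg.n_phon) if trial.phon_clamp is None else np.asarray(trial.phon_clamp, dtype=float)
    ctx = np.zeros(cfg.n_context) if trial.context is None else np.asarray(trial.context, dtype=float)
    tgt = np.asarray(trial.target, dtype=float)
    return orth, trial.orth_input is not None, clamp, trial.phon_clamp is not None, ctx, tgt


def settle(net: Network, trial: TrialSpec) -> Trajectory:
    """Run the settling dynamics for one trial and return the trajectory."""
    cfg = net.config
    orth, has_orth, clamp, has_clamp, ctx, tgt = _trial_arrays(net, trial)
    T = cfg.settle_steps
    P = np.empty((T + 1, cfg.n_phon))
    C = np.empty((T + 1, cfg.n_cleanup))
    h = np.empty(cfg.n_hidden)
    _kernels.forward(
        *(getattr(net, n) for n in _WEIGHT_NAMES),
        orth, has_orth, clamp, has_clamp, ctx,
        T, cfg.clamp_steps, cfg.target_steps, cfg.a_init, tgt, 0.0,
        cfg.error_margin,
        P, C, h,
    )
    if not np.all(np.isfinite(P)):
        raise FloatingPointError("non-finite activations during settling")
    return Trajectory(P, C, h, cfg)


def trial_loss(trajectory: Trajectory, trial: TrialSpec) -> float:
    """Scaled cross-entropy over the final target_steps steps.

    Activations are clipped to [EPS, 1-EPS] inside the logs; units
    within the configured error margin of their target contribute
    nothing (margin 0 gives plain cross-entropy).
    """
    cfg = trajectory.config
    tgt = np.asarray(trial.target, dtype=float)
    window = trajectory.phon[cfg.settle_steps - cfg.target_steps + 1:]
    a = np.clip(window, EPS, 1.0 - EPS)
    ce = -(tgt * np.log(a) + (1.0 - tgt) * np.log(1.0 - a))
    ce[np.abs(window - tgt) <= cfg.error_margin] = 0.0
    return float(trial.error_scale * ce.sum())


def _deltas(net: Network, trial: TrialSpec):
    cfg = net.config
    orth, has_orth, clamp, has_clamp, ctx, tgt = _trial_arrays(net, trial)
    T = cfg.settle_steps
    P = np.empty((T + 1, cfg.n_phon))
    C = np.empty((T + 1, cfg.n_cleanup))
    h = np.empty(cfg.n_hidden)
    loss = _kernels.forward(
        *(getattr(net, n) for n in _WEIGHT_NAMES),
        orth, has_orth, clamp, has_clamp, ctx,
        T, cfg.clamp_steps, cfg.target_steps, cfg.a_init, tgt, trial.error_scale,
        cfg.error_margin,
        P, C, h,
    )
    Dp = np.zeros((T + 1, cfg.n_phon))
    Dc = np.zeros((T + 1, cfg.n_cleanup))
    dh = np.zeros(cfg.n_hidden)
    _kernels.backward_deltas(
        net.W_pp, net.W_cp, net.W_pc, net.W_hp,
        has_clamp, T, cfg.clamp_steps, cfg.target_steps, tgt, trial.error_scale,
        cfg.error_margin,
        P, C, h, has_orth,
        Dp, Dc, dh,
    )
    return loss, orth, has_orth, ctx, P, C, h, Dp, Dc, dh


def train_trial(net: Network, trial: TrialSpec) -> tuple[Network, float]:
    """One BPTT gradient-descent update at the configured learning rate.

    The network is updated in place and returned; the loss is computed
    with the pre-update weights.
    """
    cfg = net.config
    loss, orth, has_orth, ctx, P, C, h, Dp, Dc, dh = _deltas(net, trial)
    _kernels.apply_update(
        *(getattr(net, n) for n in _WEIGHT_NAMES),
        orth, has_orth, ctx, cfg.settle_steps, cfg.learning_rate, cfg.delta_clip,
        P, C, h, Dp, Dc, dh,
    )
    if not np.isfinite(loss):
        raise FloatingPointError("non-finite loss")
    return net, float(loss)


def trial_gradients(net: Network, trial: TrialSpec) -> tuple[dict[str, np.ndarray], float]:
    """Analytic BPTT gradients of the trial loss for every weight block."""
    cfg = net.config
    loss, orth, has_orth, ctx, P, C, h, Dp, Dc, dh = _deltas(net, trial)
    grads = {name: np.zeros_like(getattr(net, name)) for name in _WEIGHT_NAMES}
    _kernels.accumulate_grads(
        orth, has_orth, ctx, cfg.settle_steps,
        P, C, h, Dp, Dc, dh,
        grads["W_oh"], grads["W_ch"], grads["b_h"], grads["W_hp"], grads["W_pp"],
        grads["W_cp"], grads["W_xp"], grads["b_p"], grads["W_pc"], grads["b_c"],
    )
    return grads, float(loss)


def run_trials(net: Network, trials: Sequence[TrialSpec]) -> np.ndarray:
    """Train on a block of trials in order (one update per trial).

    Packs the block into contiguous arrays and hands it to the compiled
    loop; returns the per-trial losses.
    """
    cfg = net.config
    n = len(trials)
    orth_mat = np.zeros((n, cfg.n_orth))
    has_orth = np.zeros(n, dtype=np.bool_)
    clamp_mat = np.zeros((n, cfg.n_phon))
    has_clamp = np.zeros(n, dtype=np.bool_)
    ctx_mat = np.zeros((n, cfg.n_context))
    tgt_mat = np.zeros((n, cfg.n_phon))
    scales = np.zeros(n)
    for i, tr in enumerate(trials):
        o, ho, cl, hc, cx, tg = _trial_arrays(net, tr)
        orth_mat[i], has_orth[i] = o, ho
        clamp_mat[i], has_clamp[i] = cl, hc
        ctx_mat[i], tgt_mat[i], scales[i] = cx, tg, tr.error_scale
    losses = np.zeros(n)
    _kernels.run_trials(
        *(getattr(net, n_) for n_ in _WEIGHT_NAMES),
        orth_mat, has_orth, clamp_mat, has_clamp, ctx_mat, tgt_mat, scales,
        cfg.settle_steps, cfg.clamp_steps, cfg.target_steps, cfg.a_init,
        cfg.learning_rate, cfg.error_margin, cfg.delta_clip, losses,
    )
    if not np.all(np.isfinite(losses)):
        raise FloatingPointError("non-finite loss during training")
    return losses


def save_network(net: Network, path) -> None:
    """Checkpoint to a single compressed .npz with the config embedded.

    The archive holds one array per weight block plus a JSON-encoded
    NetConfig under the key ``config``.
    """
    import json

    arrays = {name: getattr(net, name) for name in _WEIGHT_NAMES}
    arrays["config"] = np.frombuffer(
        json.dumps(net.config.__dict__).encode(), dtype=np.uint8)
    np.savez_compressed(path, **arrays)


def load_network(path) -> Network:
    """Restore a checkpoint written by :func:`save_network`."""
    import json

    with np.load(path) as data:
        config = NetConfig(**json.loads(bytes(data["config"]).decode()))
        return Network(config, *(data[name].copy() for name in _WEIGHT_NAMES))
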