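"""Training regimes: speech phase, reading phase, and the named conditions.

Simulated learners first acquire spoken word forms (the *speech phase*:
a pronunciation is clamped on the phonological layer and the network
must maintain it after the clamp is removed), then learn to read (the
*reading phase*: spelling on the orthographic input, pronunciation as
the target), with one speech trial per word interleaved with the
reading trials of every epoch so spoken vocabulary is maintained.

Six named conditions differ in which dialect supplies the speech and
reading targets and in how the two dialect context units are used:

========================  ==============  ===============  ================
condition                 speech targets  reading targets  context units
========================  ==============  ===============  ================
mae_match                 MAE             MAE              never
aae_match                 AAE             AAE              never
mismatch                  AAE             MAE              never
bidialectal_none          AAE+MAE (half)  MAE              never
bidialectal_early         AAE+MAE (half)  MAE              whole reading phase
bidialectal_late          AAE+MAE (half)  MAE              second half
========================  ==============  ===============  ================

In bi-dialectal conditions each Contrastive word has two speech target
variants (AAE and MAE), each carrying half the word's frequency; the
variant presented in a given epoch is drawn at random so each word still
appears exactly once per trial type per epoch.

Cross-entropy error is scaled by sqrt(word frequency), normalised by the
corpus mean of sqrt(frequency) so the learning rate is independent of
the frequency scale; reading trials use 1/10 of the speech scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .encoding import encode_orthography, encode_phonology, n_orth_units, n_phon_units
from .network import NetConfig, Network, _WEIGHT_NAMES, init_network
from .rules import DialectCorpus

__all__ = [
    "TrainingCondition", "CONDITIONS", "PhaseReport", "CorpusPatterns",
    "run_speech_phase", "run_reading_phase", "run_condition", "run_condition_suite",
    "READING_ERROR_RATIO", "desk_config",
]

#: reading-trial error scale relative to speech trials
READING_ERROR_RATIO = 0.1

AAE_UNIT, MAE_UNIT = 0, 1

_SCHEDULES = ("never", "from_epoch_0", "from_half")


@dataclass(frozen=True)
class TrainingCondition:
    """A named regime tying together speech targets, reading targets, and
    the context-unit schedule."""

    name: str
    speech_targets: str      # "mae", "aae", or "both"
    reading_targets: str     # "mae" or "aae"
    context_schedule: str    # "never", "from_epoch_0", "from_half"
    freq_split: str = "sqrt_half"   # bidialectal: sqrt(f/2) vs sqrt(f)/2

    def __post_init__(self) -> None:
        if self.speech_targets not in ("mae", "aae", "both"):
            raise ValueError(f"bad speech_targets {self.speech_targets!r}")
        if self.reading_targets not in ("mae", "aae"):
            raise ValueError(f"bad reading_targets {self.reading_targets!r}")
        if self.context_schedule not in _SCHEDULES:
            raise ValueError(f"bad context_schedule {self.context_schedule!r}")
        if self.speech_targets == "both" and self.reading_targets != "mae":
            raise ValueError("bi-dialectal conditions read MAE targets")
        if self.name == "mismatch" and self.reading_targets != "mae":
            raise ValueError("mismatch reads MAE targets")

    @property
    def bidialectal(self) -> bool:
        return self.speech_targets == "both"

    def context_active(self, epoch: int, total_epochs: int) -> bool:
        if self.context_schedule == "never":
            return False
        if self.context_schedule == "from_epoch_0":
            return True
        return epoch >= total_epochs // 2


CONDITIONS: dict[str, TrainingCondition] = {
    c.name: c
    for c in (
        TrainingCondition("mae_match", "mae", "mae", "never"),
        TrainingCondition("aae_match", "aae", "aae", "never"),
        TrainingCondition("mismatch", "aae", "mae", "never"),
        TrainingCondition("bidialectal_none", "both", "mae", "never"),
        TrainingCondition("bidialectal_early", "both", "mae", "from_epoch_0"),
        TrainingCondition("bidialectal_late", "both", "mae", "from_half"),
    )
}


def desk_config(corpus: DialectCorpus, seed: int = 0, learning_rate: float = 0.1,
                delta_clip: float = 0.0) -> NetConfig:
    """Desk-scale network configuration sized to a corpus inventory.

    Uses the standard layer layout (10 phoneme slots, 12 letter slots,
    50 hidden, 20 cleanup, 2 context units) over the corpus's own
    phoneme inventory, with the shortened 8/4/2 settling schedule, a
    0.1 error radius, and the learning rate tuned for few-hundred-word
    corpora.
    """
    return NetConfig(
        n_orth=n_orth_units(),
        n_phon=n_phon_units(corpus.inventory),
        settle_steps=8, clamp_steps=4, target_steps=2,
        learning_rate=learning_rate, error_margin=0.1, delta_clip=delta_clip,
        seed=seed,
    )


class CorpusPatterns:
    """Precomputed slot patterns and error scales for one dialect corpus.

    Error scales are sqrt(frequency) normalised by the corpus mean of
    sqrt(frequency), then capped at `scale_cap` (compressing the few
    highest-frequency words, which otherwise dominate online updates);
    reading scales are exactly 1/10 of speech scales.
    """

    def __init__(self, corpus: DialectCorpus, scale_cap: float = 3.0):
        inv = corpus.inventory
        self.corpus = corpus
        self.n_words = len(corpus)
        self.spellings = [w.spelling for w in corpus]
        self.contrastive = np.array([w.contrastive for w in corpus], dtype=bool)
        self.orth = np.stack([encode_orthography(w.spelling) for w in corpus])
        self.phon_mae = np.stack([encode_phonology(w.mae_phonemes, inv) for w in corpus])
        self.phon_aae = np.stack([encode_phonology(w.aae_phonemes, inv) for w in corpus])
        freq = np.array([w.frequency for w in corpus])
        root = np.sqrt(freq)
        cap = scale_cap if scale_cap > 0 else np.inf
        self.speech_scale = np.minimum(root / root.mean(), cap)
        self.speech_scale_half = {
            "sqrt_half": np.minimum(np.sqrt(freq / 2.0) / root.mean(), cap),
            "half_sqrt": np.minimum((root / 2.0) / root.mean(), cap),
        }
        self.reading_scale = self.speech_scale * READING_ERROR_RATIO

    def phon(self, dialect: str) -> np.ndarray:
        return {"mae": self.phon_mae, "aae": self.phon_aae}[dialect]


@dataclass
class PhaseReport:
    """Per-epoch accuracies and loss for one phase of one run."""

    condition: str
    phase: str               # "speech" or "reading"
    seed: int
    rows: list[dict] = field(default_factory=list)
    termination_epoch: int | None = None
    reached_criterion: bool | None = None

    def log(self, **row) -> None:
        for key, value in row.items():
            if key.endswith("accuracy") and value is not None and not (0.0 <= value <= 100.0):
                raise ValueError(f"{key}={value} outside [0, 100]")
        self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows)
        df.insert(0, "condition", self.condition)
        df.insert(1, "phase", self.phase)
        df.insert(2, "seed", self.seed)
        return df

    @property
    def final(self) -> dict:
        return self.rows[-1]


def _weights(net: Network):
    return tuple(getattr(net, n) for n in _WEIGHT_NAMES)


def _decode_correct(final_phon: np.ndarray, targets: np.ndarray,
                    hi: float = 0.75, lo: float = 0.25) -> np.ndarray:
    """Word-level correctness of a batch of final activations.

    A word is correct when every target unit exceeds `hi` and every
    other unit (including those of empty slots) is below `lo` — i.e.
    the decoded string equals the target and is well-formed.
    """
    on = targets > 0.5
    hit = np.all(np.where(on, final_phon > hi, final_phon < lo), axis=1)
    return hit


def _settle_block(net: Network, orth_mat, has_orth, clamp_mat, has_clamp, ctx_mat, tgt_mat):
    cfg = net.config
    n = tgt_mat.shape[0]
    final_phon = np.empty((n, cfg.n_phon))
    losses = np.empty(n)
    _kernels.settle_batch(
        *_weights(net),
        orth_mat, has_orth, clamp_mat, has_clamp, ctx_mat, tgt_mat,
        cfg.settle_steps, cfg.clamp_steps, cfg.target_steps, cfg.a_init,
        cfg.error_margin,
        final_phon, losses,
    )
    return final_phon, losses


def _zeros_ctx(n: int) -> np.ndarray:
    return np.zeros((n, 2))


def speech_eval_accuracy(net: Network, patterns: CorpusPatterns,
                         condition: TrainingCondition) -> float:
    """Percent of speech (maintenance) items reproduced after the clamp.

    In bi-dialectal conditions every Contrastive word is tested on both
    pronunciation variants; context units stay off, as in speech-phase
    training.
    """
    if condition.bidialectal:
        # every word tested on AAE maintenance; Contrastive words also on
        # AAE-input -> MAE-output conversion
        con = patterns.contrastive
        clamp = np.concatenate([patterns.phon_aae, patterns.phon_aae[con]])
        tgt = np.concatenate([patterns.phon_aae, patterns.phon_mae[con]])
    else:
        clamp = tgt = patterns.phon(condition.speech_targets)
    n = tgt.shape[0]
    orth = np.zeros((n, net.config.n_orth))
    has_orth = np.zeros(n, dtype=np.bool_)
    has_clamp = np.ones(n, dtype=np.bool_)
    final, _ = _settle_block(net, orth, has_orth, clamp, has_clamp, _zeros_ctx(n), tgt)
    return 100.0 * _decode_correct(final, tgt).mean()


def reading_eval(net: Network, patterns: CorpusPatterns, dialect: str,
                 context_on: bool = False):
    """Batch reading test: settle on each spelling, score at 0.75/0.25.

    Returns (correct mask, unscaled cross-entropy per word).  When
    `context_on`, the MAE context unit is lit, as on reading trials in
    context conditions.
    """
    tgt = patterns.phon(dialect)
    n = tgt.shape[0]
    clamp = np.zeros_like(tgt)
    has_clamp = np.zeros(n, dtype=np.bool_)
    has_orth = np.ones(n, dtype=np.bool_)
    ctx = _zeros_ctx(n)
    if context_on:
        ctx[:, MAE_UNIT] = 1.0
    final, ce = _settle_block(net, patterns.orth, has_orth, clamp, has_clamp, ctx, tgt)
    return _decode_correct(final, tgt), ce


def _run_block(net: Network, orth_mat, has_orth, clamp_mat, has_clamp, ctx_mat,
               tgt_mat, scales) -> np.ndarray:
    cfg = net.config
    losses = np.zeros(tgt_mat.shape[0])
    _kernels.run_trials(
        *_weights(net),
        orth_mat, has_orth, clamp_mat, has_clamp, ctx_mat, tgt_mat, scales,
        cfg.settle_steps, cfg.clamp_steps, cfg.target_steps, cfg.a_init,
        cfg.learning_rate, cfg.error_margin, cfg.delta_clip, losses,
    )
    return losses


def _speech_epoch_arrays(patterns: CorpusPatterns, condition: TrainingCondition,
                         rng: np.random.Generator, context_active: bool = False):
    """Clamps, targets, scales and contexts for one epoch of speech trials.

    Non-bi-dialectal: the speech-dialect pronunciation is both the
    clamped input and the target, at full frequency scale.

    Bi-dialectal: the clamped input is always the AAE pronunciation; the
    target for a Contrastive word is one of the two dialect variants
    (drawn 50/50) at the half-frequency scale, so the same input must
    yield different outputs on different trials — either maintained
    (AAE) or converted (MAE).  Non-contrastive words keep their single
    shared form.  Context units are only lit when the schedule is active
    (reading phase of context conditions): the unit of the target
    dialect for Contrastive words, the MAE unit for Non-contrastive
    words.
    """
    n = patterns.n_words
    ctx = _zeros_ctx(n)
    if not condition.bidialectal:
        tgt = patterns.phon(condition.speech_targets)
        scales = patterns.speech_scale.copy()
        if context_active:
            unit = MAE_UNIT if condition.speech_targets == "mae" else AAE_UNIT
            ctx[:, unit] = 1.0
        return tgt, tgt, scales, ctx

    use_mae = rng.random(n) < 0.5
    use_mae &= patterns.contrastive  # non-contrastive words have one form
    clamp = patterns.phon_aae
    tgt = np.where(use_mae[:, None], patterns.phon_mae, patterns.phon_aae)
    half = patterns.speech_scale_half[condition.freq_split]
    scales = np.where(patterns.contrastive, half, patterns.speech_scale)
    if context_active:
        ctx[np.arange(n), np.where(use_mae | ~patterns.contrastive, MAE_UNIT, AAE_UNIT)] = 1.0
    return clamp, tgt, scales, ctx


def run_speech_phase(
    net: Network,
    corpus: DialectCorpus | CorpusPatterns,
    condition: TrainingCondition,
    criterion: float = 95.0,
    seed: int = 0,
    max_epochs: int = 2000,
    epoch_cap: int | None = None,
) -> tuple[Network, PhaseReport]:
    """Train pattern maintenance until accuracy reaches `criterion` %.

    Each word is presented once per epoch in seeded random order.  The
    phase stops at the first epoch whose post-epoch accuracy meets the
    criterion, at `epoch_cap` (bi-dialectal conditions: matched to a
    reference condition's epoch count), or at `max_epochs` with a
    warning flag in the report.
    """
    if not 0.0 < criterion <= 100.0:
        raise ValueError("criterion must be in (0, 100]")
    patterns = corpus if isinstance(corpus, CorpusPatterns) else CorpusPatterns(corpus)
    rng = np.random.default_rng(seed)
    report = PhaseReport(condition.name, "speech", seed)
    limit = min(max_epochs, epoch_cap) if epoch_cap is not None else max_epochs
    n = patterns.n_words
    orth = np.zeros((n, net.config.n_orth))
    has_orth = np.zeros(n, dtype=np.bool_)
    has_clamp = np.ones(n, dtype=np.bool_)

    reached = False
    epoch = 0
    for epoch in range(limit):
        clamp, tgt, scales, ctx = _speech_epoch_arrays(patterns, condition, rng)
        order = rng.permutation(n)
        losses = _run_block(net, orth, has_orth, clamp[order], has_clamp, ctx[order],
                            tgt[order], scales[order])
        acc = speech_eval_accuracy(net, patterns, condition)
        report.log(epoch=epoch, speech_accuracy=acc, mean_loss=float(losses.mean()))
        if acc >= criterion:
            reached = True
            break
    report.termination_epoch = epoch + 1
    report.reached_criterion = reached
    return net, report


def _reading_epoch_arrays(patterns: CorpusPatterns, condition: TrainingCondition,
                          rng: np.random.Generator, epoch: int, epochs: int):
    """Packed trial block for one reading-phase epoch, pre-shuffle.

    Rows 0..n-1 are reading trials (orthographic input, reading-dialect
    target at 1/10 scale), rows n..2n-1 are the interleaved speech
    trials.  Returned as (orth, has_orth, clamp, has_clamp, ctx, tgt,
    scales, word_index).
    """
    n = patterns.n_words
    active = condition.context_active(epoch, epochs)
    sp_clamp, sp_tgt, sp_scales, sp_ctx = _speech_epoch_arrays(patterns, condition, rng, active)
    rd_ctx = _zeros_ctx(n)
    if active:
        rd_ctx[:, MAE_UNIT] = 1.0
    read_tgt = patterns.phon(condition.reading_targets)
    orth_mat = np.concatenate([patterns.orth, np.zeros_like(patterns.orth)])
    has_orth = np.concatenate([np.ones(n, dtype=np.bool_), np.zeros(n, dtype=np.bool_)])
    clamp_mat = np.concatenate([np.zeros_like(sp_tgt), sp_clamp])
    has_clamp = ~has_orth
    ctx_mat = np.concatenate([rd_ctx, sp_ctx])
    tgt_mat = np.concatenate([read_tgt, sp_tgt])
    scales = np.concatenate([patterns.reading_scale, sp_scales])
    word_index = np.concatenate([np.arange(n), np.arange(n)])
    return orth_mat, has_orth, clamp_mat, has_clamp, ctx_mat, tgt_mat, scales, word_index


def run_reading_phase(
    net: Network,
    corpus: DialectCorpus | CorpusPatterns,
    condition: TrainingCondition,
    epochs: int = 1000,
    seed: int = 0,
    eval_every: int = 5,
) -> tuple[Network, PhaseReport]:
    """Interleaved reading + speech training for a fixed number of epochs.

    Every epoch holds one reading trial and one speech trial per word in
    a single seeded shuffle.  Reading trials present the spelling and
    the reading-dialect pronunciation at 1/10 of the speech error scale;
    speech trials continue exactly as in the speech phase.  When the
    condition's context schedule is active, reading trials light the MAE
    unit and speech trials light the unit of the presented dialect.
    """
    if epochs <= 0:
        raise ValueError("epochs must be positive")
    patterns = corpus if isinstance(corpus, CorpusPatterns) else CorpusPatterns(corpus)
    rng = np.random.default_rng(seed)
    report = PhaseReport(condition.name, "reading", seed)
    n = patterns.n_words

    for epoch in range(epochs):
        active = condition.context_active(epoch, epochs)
        (orth_mat, has_orth, clamp_mat, has_clamp,
         ctx_mat, tgt_mat, scales, _) = _reading_epoch_arrays(
            patterns, condition, rng, epoch, epochs)

        order = rng.permutation(2 * n)
        losses = _run_block(net, orth_mat[order], has_orth[order], clamp_mat[order],
                            has_clamp[order], ctx_mat[order], tgt_mat[order], scales[order])

        if epoch % eval_every == 0 or epoch == epochs - 1:
            correct, ce = reading_eval(net, patterns, condition.reading_targets, active)
            con = patterns.contrastive
            report.log(
                epoch=epoch,
                reading_accuracy=100.0 * correct.mean(),
                reading_accuracy_contrastive=100.0 * correct[con].mean() if con.any() else None,
                reading_accuracy_non_contrastive=100.0 * correct[~con].mean() if (~con).any() else None,
                speech_accuracy=speech_eval_accuracy(net, patterns, condition),
                mean_ce=float(ce.mean()),
                mean_ce_contrastive=float(ce[con].mean()) if con.any() else None,
                mean_ce_non_contrastive=float(ce[~con].mean()) if (~con).any() else None,
                mean_loss=float(losses.mean()),
            )
    report.termination_epoch = epochs
    return net, report


def run_condition(
    corpus: DialectCorpus | CorpusPatterns,
    condition: TrainingCondition | str,
    seed: int = 0,
    config: NetConfig | None = None,
    reading_epochs: int = 1000,
    criterion: float = 95.0,
    speech_epoch_cap: int | None = None,
    eval_every: int = 5,
) -> dict:
    """One complete run: init, speech phase, reading phase.

    Returns the trained network and both phase reports.  Bi-dialectal
    conditions should pass `speech_epoch_cap` (the speech epoch count of
    the matched single-dialect run).
    """
    if isinstance(condition, str):
        condition = CONDITIONS[condition]
    patterns = corpus if isinstance(corpus, CorpusPatterns) else CorpusPatterns(corpus)
    cfg = config or desk_config(patterns.corpus, seed=seed)
    if cfg.seed != seed:
        cfg = replace(cfg, seed=seed)
    net = init_network(cfg)
    net, speech_report = run_speech_phase(
        net, patterns, condition, criterion=criterion, seed=seed,
        epoch_cap=speech_epoch_cap,
    )
    net, reading_report = run_reading_phase(
        net, patterns, condition, epochs=reading_epochs, seed=seed,
        eval_every=eval_every,
    )
    return {
        "condition": condition.name,
        "seed": seed,
        "network": net,
        "speech_report": speech_report,
        "reading_report": reading_report,
    }


def run_condition_suite(
    corpus: DialectCorpus | CorpusPatterns,
    conditions: Sequence[TrainingCondition | str],
    seeds: Sequence[int] = (0, 1, 2),
    config: NetConfig | None = None,
    reading_epochs: int = 1000,
    criterion: float = 95.0,
    eval_every: int = 5,
) -> list[dict]:
    """Run each condition once per seed (three by default, so condition
    means average over independent initialisations).

    Bi-dialectal speech phases are capped at the epoch count of the
    same-seed AAE speech phase (taken from the mismatch run when
    present, otherwise measured with a dedicated run), mirroring the
    matched-epochs design.
    """
    if len(set(seeds)) != len(seeds):
        raise ValueError("seeds must be distinct")
    conds = [CONDITIONS[c] if isinstance(c, str) else c for c in conditions]
    patterns = corpus if isinstance(corpus, CorpusPatterns) else CorpusPatterns(corpus)
    results: list[dict] = []
    aae_speech_epochs: dict[int, int] = {}

    def _cap_for(seed: int) -> int:
        if seed not in aae_speech_epochs:
            cfg = replace(config or desk_config(patterns.corpus, seed=seed), seed=seed)
            net = init_network(cfg)
            _, rep = run_speech_phase(net, patterns, CONDITIONS["mismatch"],
                                      criterion=criterion, seed=seed)
            aae_speech_epochs[seed] = rep.termination_epoch
        return aae_speech_epochs[seed]

    ordered = sorted(conds, key=lambda c: c.bidialectal)  # single-dialect first
    for cond in ordered:
        for seed in seeds:
            cap = _cap_for(seed) if cond.bidialectal else None
            result = run_condition(
                patterns, cond, seed=seed, config=config,
                reading_epochs=reading_epochs, criterion=criterion,
                speech_epoch_cap=cap, eval_every=eval_every,
            )
            if cond.name == "mismatch":
                aae_speech_epochs.setdefault(seed, result["speech_report"].termination_epoch)
            results.append(result)
    return results
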