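"""Scoring trained networks and building matched test-pair sets.

Reading accuracy uses the 0.75/0.25 criterion: a word is correct when
every unit of its target pronunciation is above 0.75 and every other
phonological unit is below 0.25 on the final settling step.  Word
difficulty is indexed by unscaled cross-entropy between the output and
the target over the final settling steps, comparable across word
classes because no frequency weighting is applied.

Contrastive/Non-contrastive comparisons use matched pairs equated on
the lexical variables used for the behavioral stimuli: log token
frequency, number of letters, and initial phoneme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .network import Network
from .rules import DialectCorpus
from .training import CorpusPatterns, PhaseReport, reading_eval

__all__ = ["EvalReport", "MatchedPairSet", "evaluate_reading", "match_pairs",
           "learning_curves", "epochs_to_reference"]


@dataclass
class EvalReport:
    """Word-level reading scores, aggregated overall and by word class."""

    overall_accuracy: float
    accuracy_contrastive: float | None
    accuracy_non_contrastive: float | None
    mean_ce_contrastive: float | None
    mean_ce_non_contrastive: float | None
    per_word: pd.DataFrame = field(repr=False)

    def to_dict(self) -> dict:
        return {
            "overall_accuracy": self.overall_accuracy,
            "accuracy_contrastive": self.accuracy_contrastive,
            "accuracy_non_contrastive": self.accuracy_non_contrastive,
            "mean_ce_contrastive": self.mean_ce_contrastive,
            "mean_ce_non_contrastive": self.mean_ce_non_contrastive,
        }


def evaluate_reading(
    net: Network,
    corpus: DialectCorpus | CorpusPatterns,
    dialect_targets: str = "mae",
    context_on: bool = False,
) -> EvalReport:
    """Score every corpus word: settle on the spelling, decode, compare.

    `context_on` lights the MAE context unit during the test, as on
    reading trials of context conditions.
    """
    patterns = corpus if isinstance(corpus, CorpusPatterns) else CorpusPatterns(corpus)
    correct, ce = reading_eval(net, patterns, dialect_targets, context_on)
    con = patterns.contrastive
    per_word = pd.DataFrame({
        "word": patterns.spellings,
        "contrastive": con,
        "correct": correct,
        "cross_entropy": ce,
    })
    return EvalReport(
        overall_accuracy=100.0 * correct.mean(),
        accuracy_contrastive=100.0 * correct[con].mean() if con.any() else None,
        accuracy_non_contrastive=100.0 * correct[~con].mean() if (~con).any() else None,
        mean_ce_contrastive=float(ce[con].mean()) if con.any() else None,
        mean_ce_non_contrastive=float(ce[~con].mean()) if (~con).any() else None,
        per_word=per_word,
    )


@dataclass
class MatchedPairSet:
    """Contrastive/Non-contrastive word pairs equated on lexical variables."""

    pairs: list[tuple[str, str]]
    logfreq_tolerance: float
    letters_tolerance: int

    def __len__(self) -> int:
        return len(self.pairs)

    def validate(self, corpus: DialectCorpus) -> None:
        used: set[str] = set()
        for c_word, n_word in self.pairs:
            cw, nw = corpus.word(c_word), corpus.word(n_word)
            if not cw.contrastive or nw.contrastive:
                raise ValueError(f"pair ({c_word}, {n_word}): wrong classes")
            if c_word in used or n_word in used:
                raise ValueError(f"word reused in pairs: {c_word}/{n_word}")
            used.update((c_word, n_word))
            dlf = abs(math.log10(cw.frequency) - math.log10(nw.frequency))
            if dlf > self.logfreq_tolerance + 1e-12:
                raise ValueError(f"pair ({c_word}, {n_word}): log-frequency gap {dlf:.3f}")
            if abs(len(c_word) - len(n_word)) > self.letters_tolerance:
                raise ValueError(f"pair ({c_word}, {n_word}): letter-count gap")
            if cw.mae_phonemes[0] != nw.mae_phonemes[0]:
                raise ValueError(f"pair ({c_word}, {n_word}): initial phonemes differ")


def match_pairs(
    corpus: DialectCorpus,
    logfreq_tolerance: float = 0.3,
    letters_tolerance: int = 0,
    seed: int = 0,
) -> MatchedPairSet:
    """Greedy seeded matching of Contrastive to Non-contrastive words.

    Contrastive words are visited in seeded random order; each takes the
    unused Non-contrastive word with the same initial (MAE) phoneme,
    letter count within tolerance, and the smallest log10-frequency gap
    within tolerance.  Unmatched words are dropped.
    """
    rng = np.random.default_rng(seed)
    contrastive = [w for w in corpus if w.contrastive]
    pool = [w for w in corpus if not w.contrastive]
    if not contrastive or not pool:
        raise ValueError("corpus must contain both word classes")
    order = rng.permutation(len(contrastive))
    available = set(range(len(pool)))
    pairs: list[tuple[str, str]] = []
    for i in order:
        cw = contrastive[i]
        best_j, best_gap = None, None
        for j in available:
            nw = pool[j]
            if nw.mae_phonemes[0] != cw.mae_phonemes[0]:
                continue
            if abs(len(nw.spelling) - len(cw.spelling)) > letters_tolerance:
                continue
            gap = abs(math.log10(cw.frequency) - math.log10(nw.frequency))
            if gap > logfreq_tolerance:
                continue
            if best_gap is None or gap < best_gap:
                best_j, best_gap = j, gap
        if best_j is not None:
            available.remove(best_j)
            pairs.append((cw.spelling, pool[best_j].spelling))
    if not pairs:
        raise ValueError("no matched pairs could be formed")
    out = MatchedPairSet(pairs, logfreq_tolerance, letters_tolerance)
    out.validate(corpus)
    return out


def learning_curves(reports: Sequence[PhaseReport]) -> pd.DataFrame:
    """Long-format accuracy table: epoch x condition x seed x word class.

    All reports must share the same epoch grid (enforced); rows carry
    one accuracy value per word class ("all", "contrastive",
    "non_contrastive").
    """
    grids = {tuple(r["epoch"] for r in rep.rows) for rep in reports}
    if len(grids) > 1:
        raise ValueError("reports do not share an epoch grid")
    records = []
    class_cols = {
        "all": "reading_accuracy",
        "contrastive": "reading_accuracy_contrastive",
        "non_contrastive": "reading_accuracy_non_contrastive",
    }
    for rep in reports:
        for row in rep.rows:
            for cls, col in class_cols.items():
                if row.get(col) is not None:
                    records.append({
                        "condition": rep.condition,
                        "seed": rep.seed,
                        "epoch": row["epoch"],
                        "word_class": cls,
                        "accuracy": row[col],
                    })
    return pd.DataFrame.from_records(records)


def epochs_to_reference(curves: pd.DataFrame, reference_accuracy: float,
                        word_class: str = "all") -> pd.Series:
    """First epoch at which each condition's mean curve reaches a level.

    Conditions that never reach it map to NaN.  Supports comparisons
    like "how much more training did the Mismatch model need to reach
    the Match models' accuracy".
    """
    sub = curves[curves.word_class == word_class]
    mean = sub.groupby(["condition", "epoch"], as_index=False)["accuracy"].mean()
    out = {}
    for cond, grp in mean.groupby("condition"):
        hit = grp[grp.accuracy >= reference_accuracy]
        out[cond] = float(hit.epoch.min()) if len(hit) else float("nan")
    return pd.Series(out, name=f"epochs_to_{reference_accuracy}")
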