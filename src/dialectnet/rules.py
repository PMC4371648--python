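"""Phonological rule engine deriving an AAE corpus from an MAE corpus.

African American English (AAE) differs from Mainstream American English
(MAE) partly in phonology; a word whose pronunciation differs between
the two dialects is called *Contrastive*.  This module rewrites MAE
pronunciations with a configurable set of AAE phonological rules.  The
default set is a reconstruction of five widely documented features:

1. ``final_devoicing``   – a word-final voiced stop after the vowel is
   devoiced (BAD /b ae d/ -> /b ae t/).
2. ``th_onset``          – pre-vocalic interdental stopping
   (THIS /dh ih s/ -> /d ih s/; THIN -> /t ih n/).
3. ``th_coda``           – post-vocalic interdental fronting
   (BATH /b ae th/ -> /b ae f/; BATHE -> /b ey v/).
4. ``cluster_reduction`` – the last consonant of a word-final cluster is
   deleted (BEST -> /b eh s/, TOLD -> /t ow l/), except velar-nasal +
   stop clusters (DRANK keeps /ng k/) and a final /s z/ after a cluster
   (BANKS keeps its /s/).
5. ``r_reduction``       – a postvocalic /r/ in the coda is deleted
   (FLOOR -> /f l ao/).

Only one rule is applied per eligible word; when several match, one is
chosen uniformly at random, which puts some variability into the AAE
corpus just as feature use varies across utterances.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .lexicon import Lexicon, LexiconEntry, LexiconError, PhonemeInventory

__all__ = [
    "PhonRule",
    "DialectWord",
    "DialectCorpus",
    "DEFAULT_RULESET",
    "default_ruleset",
    "applicable_rules",
    "build_aae_corpus",
    "homophone_report",
    "ruleset_from_config",
    "rule_cluster_reduction",
    "rule_th_substitution",
]

VOICED_STOPS = {"B": "P", "D": "T", "G": "K"}
_VOWELS = PhonemeInventory().vowel_set


def _vowel_index(phonemes: Sequence[str], vowels=frozenset(_VOWELS)) -> int:
    for i, p in enumerate(phonemes):
        if p in vowels:
            return i
    raise LexiconError(f"no vowel in {phonemes!r}")


@dataclass(frozen=True)
class PhonRule:
    """A context-conditioned rewrite on a monosyllabic phoneme string.

    `match` must hold exactly when `transform` would change the string,
    and `transform` output must remain a valid monosyllabic string.
    """

    id: str
    match: Callable[[tuple[str, ...]], bool]
    transform: Callable[[tuple[str, ...]], tuple[str, ...]]

    def apply(self, phonemes: tuple[str, ...]) -> tuple[str, ...]:
        if not self.match(phonemes):
            return phonemes
        out = self.transform(phonemes)
        if out == phonemes:
            raise LexiconError(f"rule {self.id} matched but did not change {phonemes!r}")
        return out


# --- rule predicates and rewrites ---------------------------------------

def _match_final_devoicing(ph: tuple[str, ...]) -> bool:
    v = _vowel_index(ph)
    return len(ph) >= 2 and ph[-1] in VOICED_STOPS and len(ph) - 2 == v


def _apply_final_devoicing(ph: tuple[str, ...]) -> tuple[str, ...]:
    return ph[:-1] + (VOICED_STOPS[ph[-1]],)


def _match_th_onset(ph: tuple[str, ...]) -> bool:
    v = _vowel_index(ph)
    return any(p in ("TH", "DH") for p in ph[:v])


def _apply_th_onset(ph: tuple[str, ...]) -> tuple[str, ...]:
    v = _vowel_index(ph)
    sub = {"TH": "T", "DH": "D"}
    return tuple(sub.get(p, p) if i < v else p for i, p in enumerate(ph))


def _match_th_coda(ph: tuple[str, ...]) -> bool:
    v = _vowel_index(ph)
    return any(p in ("TH", "DH") for p in ph[v + 1:])


def _apply_th_coda(ph: tuple[str, ...]) -> tuple[str, ...]:
    v = _vowel_index(ph)
    sub = {"TH": "F", "DH": "V"}
    return tuple(sub.get(p, p) if i > v else p for i, p in enumerate(ph))


def _match_cluster_reduction(ph: tuple[str, ...]) -> bool:
    v = _vowel_index(ph)
    coda = ph[v + 1:]
    if len(coda) < 2:
        return False
    # velar-nasal + stop clusters are not reduced (DRANK, SINK, PINK)
    if coda[-2] == "NG" and coda[-1] in ("K", "G"):
        return False
    # a final /s z/ after a cluster is kept (BANKS, BUMPS, TANKS)
    if coda[-1] in ("S", "Z") and len(coda) >= 3:
        return False
    return True


def _apply_cluster_reduction(ph: tuple[str, ...]) -> tuple[str, ...]:
    return ph[:-1]


def _match_r_reduction(ph: tuple[str, ...]) -> bool:
    v = _vowel_index(ph)
    return v + 1 < len(ph) and ph[v + 1] == "R"


def _apply_r_reduction(ph: tuple[str, ...]) -> tuple[str, ...]:
    v = _vowel_index(ph)
    return ph[: v + 1] + ph[v + 2:]


def default_ruleset() -> tuple[PhonRule, ...]:
    return (
        PhonRule("final_devoicing", _match_final_devoicing, _apply_final_devoicing),
        PhonRule("th_onset", _match_th_onset, _apply_th_onset),
        PhonRule("th_coda", _match_th_coda, _apply_th_coda),
        PhonRule("cluster_reduction", _match_cluster_reduction, _apply_cluster_reduction),
        PhonRule("r_reduction", _match_r_reduction, _apply_r_reduction),
    )


DEFAULT_RULESET = default_ruleset()


def rule_cluster_reduction(phonemes: tuple[str, ...]) -> tuple[str, ...]:
    """Apply final consonant-cluster reduction, identity when ineligible."""
    rule = DEFAULT_RULESET[3]
    return rule.apply(phonemes) if rule.match(phonemes) else phonemes


def rule_th_substitution(phonemes: tuple[str, ...]) -> tuple[str, ...]:
    """Apply interdental substitution (onset first, else coda); identity when ineligible."""
    onset, coda = DEFAULT_RULESET[1], DEFAULT_RULESET[2]
    if onset.match(phonemes):
        return onset.apply(phonemes)
    if coda.match(phonemes):
        return coda.apply(phonemes)
    return phonemes


# --- corpus construction -------------------------------------------------

@dataclass(frozen=True)
class DialectWord:
    spelling: str
    mae_phonemes: tuple[str, ...]
    aae_phonemes: tuple[str, ...]
    frequency: float
    rule_applied: str | None

    @property
    def contrastive(self) -> bool:
        return self.mae_phonemes != self.aae_phonemes


@dataclass
class DialectCorpus:
    """Paired MAE/AAE pronunciations for every word of a lexicon."""

    words: list[DialectWord]
    inventory: PhonemeInventory

    def __post_init__(self) -> None:
        for w in self.words:
            if (w.rule_applied is not None) != w.contrastive:
                raise LexiconError(f"{w.spelling}: rule/contrastive flags inconsistent")

    def __len__(self) -> int:
        return len(self.words)

    def __iter__(self):
        return iter(self.words)

    @property
    def contrastive_fraction(self) -> float:
        return sum(w.contrastive for w in self.words) / len(self.words)

    def word(self, spelling: str) -> DialectWord:
        for w in self.words:
            if w.spelling == spelling:
                return w
        raise KeyError(spelling)


def applicable_rules(
    entry: LexiconEntry, ruleset: Sequence[PhonRule] = DEFAULT_RULESET
) -> list[str]:
    """Ids of every rule whose context predicate holds for the entry."""
    if not ruleset:
        return []
    return [r.id for r in ruleset if r.match(entry.phonemes)]


def build_aae_corpus(
    lexicon: Lexicon,
    ruleset: Sequence[PhonRule] = DEFAULT_RULESET,
    seed: int = 0,
) -> DialectCorpus:
    """Rewrite each eligible word with one randomly chosen applicable rule.

    Words with no applicable rule are copied unchanged (Non-contrastive);
    the draw among applicable rules is uniform and reproducible from
    `seed`.  Rule outputs are re-validated against the lexicon entry
    invariants so a misconfigured rule fails loudly.
    """
    rng = np.random.default_rng(seed)
    by_id = {r.id: r for r in ruleset}
    words = []
    for e in lexicon.entries:
        ids = applicable_rules(e, ruleset)
        if ids:
            rule = by_id[ids[int(rng.integers(len(ids)))]]
            aae = rule.apply(e.phonemes)
            try:
                LexiconEntry(e.spelling, aae, e.frequency).validate(lexicon.inventory)
            except LexiconError as err:
                raise LexiconError(
                    f"rule {rule.id} produced invalid output for {e.spelling!r}: {err}"
                ) from err
            words.append(DialectWord(e.spelling, e.phonemes, aae, e.frequency, rule.id))
        else:
            words.append(DialectWord(e.spelling, e.phonemes, e.phonemes, e.frequency, None))
    return DialectCorpus(words, lexicon.inventory)


def ruleset_from_config(config: Sequence[dict]) -> tuple[PhonRule, ...]:
    """Build a ruleset from a declarative description (e.g. parsed YAML).

    Each entry is a mapping with an ``id`` and a ``kind``:

    - ``substitution``: ``position`` ("onset" or "coda") and a
      ``segments`` mapping of phoneme rewrites, e.g.
      ``{id: th_onset, kind: substitution, position: onset,
      segments: {TH: T, DH: D}}``;
    - ``final_cluster_reduction``: deletes the last consonant of a
      word-final cluster, with the velar-nasal and final-s exemptions;
    - ``final_devoicing``: devoices a single post-vocalic final stop;
    - ``postvocalic_deletion``: deletes a given ``segment`` directly
      after the vowel (default "R").
    """
    out: list[PhonRule] = []
    for entry in config:
        rid, kind = entry["id"], entry["kind"]
        if kind == "substitution":
            position = entry["position"]
            if position not in ("onset", "coda"):
                raise LexiconError(f"rule {rid}: bad position {position!r}")
            segments = {str(k): str(v) for k, v in entry["segments"].items()}
            onset = position == "onset"

            def match(ph, _s=segments, _on=onset):
                v = _vowel_index(ph)
                span = ph[:v] if _on else ph[v + 1:]
                return any(p in _s for p in span)

            def transform(ph, _s=segments, _on=onset):
                v = _vowel_index(ph)
                if _on:
                    return tuple(_s.get(p, p) if i < v else p for i, p in enumerate(ph))
                return tuple(_s.get(p, p) if i > v else p for i, p in enumerate(ph))

            out.append(PhonRule(rid, match, transform))
        elif kind == "final_cluster_reduction":
            out.append(PhonRule(rid, _match_cluster_reduction, _apply_cluster_reduction))
        elif kind == "final_devoicing":
            out.append(PhonRule(rid, _match_final_devoicing, _apply_final_devoicing))
        elif kind == "postvocalic_deletion":
            segment = str(entry.get("segment", "R"))

            def match_pv(ph, _seg=segment):
                v = _vowel_index(ph)
                return v + 1 < len(ph) and ph[v + 1] == _seg

            def transform_pv(ph):
                v = _vowel_index(ph)
                return ph[: v + 1] + ph[v + 2:]

            out.append(PhonRule(rid, match_pv, transform_pv))
        else:
            raise LexiconError(f"rule {rid}: unknown kind {kind!r}")
    return tuple(out)


def homophone_report(corpus: DialectCorpus) -> list[set[str]]:
    """Spelling sets whose AAE pronunciations collide (size >= 2 only).

    Final-consonant deletion creates homophones (COLD /k ow l/ with
    COAL); groups are returned sorted by pronunciation for determinism.
    """
    groups: dict[tuple[str, ...], set[str]] = {}
    for w in corpus.words:
        groups.setdefault(w.aae_phonemes, set()).add(w.spelling)
    return [g for _, g in sorted(groups.items()) if len(g) >= 2]
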