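"""Synthetic monosyllabic lexicons with English-like structure.

The generator produces artificial CV(C) lexicons that have the
statistical properties the simulations assume about the real training
corpus: monosyllabic phoneme strings over a subset of the ARPAbet
inventory, spellings derived from phonemes through a grapheme map with
tunable spelling–sound consistency, Zipf-distributed token frequencies
above the corpus-inclusion floor, and a controlled fraction of words
eligible for at least one AAE rule (about half, mirroring the 51%
design point of the real corpus).

The inventories are deliberately small (22 onsets, 8 vowels, 24 codas)
so that a 50-hidden-unit network can learn a few-hundred-word lexicon in
minutes.  They are a test-scale idealisation, not a claim about English
phonotactics.
"""

from __future__ import annotations

import hashlib
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .lexicon import Lexicon, LexiconEntry, LexiconError, PhonemeInventory, write_lexicon_tsv
from .rules import DEFAULT_RULESET, applicable_rules, build_aae_corpus

__all__ = ["GenSpec", "generate_lexicon", "generate_fixture_suite", "rule_eligible_fraction"]

# onset / vowel / coda building blocks (phoneme tuples)
DEFAULT_ONSETS: tuple[tuple[str, ...], ...] = (
    (), ("B",), ("D",), ("F",), ("G",), ("K",), ("L",), ("M",), ("N",),
    ("P",), ("R",), ("S",), ("T",), ("W",), ("TH",), ("DH",),
    ("B", "L"), ("D", "R"), ("F", "L"), ("G", "R"), ("S", "T"), ("S", "P"),
)
DEFAULT_VOWELS: tuple[str, ...] = ("AA", "AE", "AH", "EH", "IH", "IY", "OW", "UW")
DEFAULT_CODAS: tuple[tuple[str, ...], ...] = (
    (), ("K",), ("L",), ("M",), ("N",), ("P",), ("S",), ("T",), ("F",), ("Z",),
    ("B",), ("D",), ("G",),                      # final voiced stops (devoicing)
    ("TH",),                                     # coda interdental
    ("N", "D"), ("S", "T"), ("S", "K"), ("L", "D"), ("N", "T"),  # reducible clusters
    ("R",), ("R", "D"),                          # postvocalic r
    ("NG", "K"), ("NG", "K", "S"), ("M", "P", "S"),  # exempt nasal-stop (+s) codas
)

# per-phoneme grapheme options: first entry is the primary spelling,
# the rest are attested alternates used to inject inconsistency
GRAPHEMES: dict[str, tuple[str, ...]] = {
    "AA": ("o", "a"), "AE": ("a",), "AH": ("u", "o"), "EH": ("e", "ea"),
    "IH": ("i",), "IY": ("ee", "ea"), "OW": ("o", "oa"), "UW": ("oo", "ew"),
    "B": ("b",), "D": ("d",), "F": ("f",), "G": ("g",), "K": ("k", "c"),
    "L": ("l",), "M": ("m",), "N": ("n",), "NG": ("n",), "P": ("p",),
    "R": ("r",), "S": ("s",), "T": ("t",), "TH": ("th",), "DH": ("th",),
    "V": ("v",), "W": ("w",), "Z": ("z", "s"),
}


def _synthetic_inventory() -> PhonemeInventory:
    used = set(DEFAULT_VOWELS)
    for seq in DEFAULT_ONSETS + DEFAULT_CODAS:
        used.update(seq)
    used.update({"V"})  # th_coda rewrites DH -> V
    return PhonemeInventory().restrict(used)


@dataclass(frozen=True)
class GenSpec:
    """Parameters of the synthetic lexicon generator.

    `consistency` is the probability that a phoneme is spelled with its
    primary grapheme; `target_rule_fraction` is the fraction of words
    eligible for at least one AAE rule, enforced by quota sampling over
    candidate onset+vowel+coda forms.
    """

    n_words: int = 300
    onsets: tuple[tuple[str, ...], ...] = DEFAULT_ONSETS
    vowels: tuple[str, ...] = DEFAULT_VOWELS
    codas: tuple[tuple[str, ...], ...] = DEFAULT_CODAS
    consistency: float = 0.85
    zipf_exponent: float = 1.0
    zipf_jitter_sd: float = 0.15
    min_frequency: float = 10.5
    target_rule_fraction: float = 0.51
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_words < 10:
            raise ValueError("n_words must be >= 10")
        if not 0.0 <= self.consistency <= 1.0:
            raise ValueError("consistency must be in [0, 1]")
        if not 0.0 <= self.target_rule_fraction <= 1.0:
            raise ValueError("target_rule_fraction must be in [0, 1]")


def _spell(phonemes: tuple[str, ...], rng: np.random.Generator, consistency: float) -> str:
    parts = []
    for p in phonemes:
        options = GRAPHEMES[p]
        if len(options) == 1 or rng.random() < consistency:
            parts.append(options[0])
        else:
            parts.append(options[1 + int(rng.integers(len(options) - 1))])
    return "".join(parts)


def rule_eligible_fraction(lexicon: Lexicon, ruleset=DEFAULT_RULESET) -> float:
    """Fraction of words with at least one applicable AAE rule."""
    return sum(bool(applicable_rules(e, ruleset)) for e in lexicon.entries) / len(lexicon)


def generate_lexicon(spec: GenSpec) -> Lexicon:
    """Draw a synthetic lexicon satisfying the generator contract.

    Candidate onset+vowel+coda forms are sampled without replacement and
    admitted against two quotas — rule-eligible and rule-ineligible — so
    the eligible fraction lands on ``target_rule_fraction`` up to
    rounding.  Spellings come from the grapheme map; a collision with an
    already-used spelling is retried with alternate graphemes, then the
    form is discarded.  Frequencies are Zipf over a random rank
    assignment with lognormal jitter, floored just above the
    corpus-inclusion threshold.
    """
    rng = np.random.default_rng(spec.seed)
    inventory = _synthetic_inventory()
    forms = [o + (v,) + c for o in spec.onsets for v in spec.vowels for c in spec.codas]
    order = rng.permutation(len(forms))

    n_eligible = round(spec.n_words * spec.target_rule_fraction)
    n_ineligible = spec.n_words - n_eligible
    quota = {True: n_eligible, False: n_ineligible}
    chosen: list[tuple[str, tuple[str, ...]]] = []
    used_spellings: set[str] = set()

    for idx in order:
        if quota[True] == 0 and quota[False] == 0:
            break
        phonemes = forms[idx]
        entry = LexiconEntry("stub", phonemes, 100.0)
        eligible = bool(applicable_rules(entry, DEFAULT_RULESET))
        if quota[eligible] == 0:
            continue
        spelling = None
        for _ in range(8):
            cand = _spell(phonemes, rng, spec.consistency)
            if cand not in used_spellings:
                spelling = cand
                break
        if spelling is None:
            continue
        used_spellings.add(spelling)
        chosen.append((spelling, phonemes))
        quota[eligible] -= 1

    if quota[True] or quota[False]:
        raise LexiconError(
            f"could not reach {spec.n_words} unique words "
            f"(eligible quota left {quota[True]}, ineligible {quota[False]})"
        )

    ranks = rng.permutation(spec.n_words) + 1
    freqs = spec.min_frequency * (spec.n_words / ranks) ** spec.zipf_exponent
    freqs = freqs * np.exp(rng.normal(0.0, spec.zipf_jitter_sd, spec.n_words))
    freqs = np.maximum(freqs, spec.min_frequency)

    entries = [
        LexiconEntry(sp, ph, float(f))
        for (sp, ph), f in zip(chosen, freqs)
    ]
    entries.sort(key=lambda e: e.spelling)
    return Lexicon(entries, inventory)


def _lexicon_bytes(lexicon: Lexicon) -> bytes:
    buf = io.StringIO()
    write_lexicon_tsv(lexicon, buf)
    return buf.getvalue().encode()


def generate_fixture_suite(seed: int = 0, out_dir: str | Path | None = None) -> dict:
    """Small canned lexicons (10, 50, 300 words) plus their AAE corpora.

    Regeneration from the same seed is byte-identical; returns the
    lexicons, dialect corpora, and content digests, optionally writing
    the TSVs under `out_dir`.
    """
    suite: dict = {}
    for n in (10, 50, 300):
        spec = GenSpec(n_words=n, target_rule_fraction=0.5 if n == 10 else 0.51, seed=seed + n)
        lex = generate_lexicon(spec)
        corpus = build_aae_corpus(lex, DEFAULT_RULESET, seed=seed + n)
        blob = _lexicon_bytes(lex)
        suite[n] = {
            "lexicon": lex,
            "corpus": corpus,
            "sha256": hashlib.sha256(blob).hexdigest(),
            "contrastive_count": sum(w.contrastive for w in corpus),
        }
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            (out / f"lexicon_{n}.tsv").write_bytes(blob)
            rows = ["word\tmae\taae\tcontrastive\trule\n"] + [
                f"{w.spelling}\t{' '.join(w.mae_phonemes)}\t{' '.join(w.aae_phonemes)}"
                f"\t{int(w.contrastive)}\t{w.rule_applied or ''}\n"
                for w in corpus
            ]
            (out / f"dialect_corpus_{n}.tsv").write_text("".join(rows))
    return suite
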