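"""Lexicon containers and readers.

The model's vocabulary is a set of monosyllabic words, each with a
spelling, a phonemic pronunciation, and a token frequency on the scale
of second-grade print-exposure norms.  Pronunciations use the ARPAbet
symbol set of the CMU Pronouncing Dictionary with stress digits removed,
which leaves 39 phonemes; with 10 positional slots this yields the
390-unit phonological layer of the network (and 26 letters x 12 slots
give the 312-unit orthographic layer).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, TextIO

__all__ = [
    "CMU_PHONEMES",
    "CMU_VOWELS",
    "PhonemeInventory",
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "read_pronunciation_dict",
    "read_frequency_table",
    "build_corpus",
    "write_lexicon_tsv",
    "read_lexicon_tsv",
]

# ARPAbet, stress-stripped: 39 symbols, 15 of them syllabic (vowels).
CMU_PHONEMES: tuple[str, ...] = (
    "AA", "AE", "AH", "AO", "AW", "AY", "B", "CH", "D", "DH",
    "EH", "ER", "EY", "F", "G", "HH", "IH", "IY", "JH", "K",
    "L", "M", "N", "NG", "OW", "OY", "P", "R", "S", "SH",
    "T", "TH", "UH", "UW", "V", "W", "Y", "Z", "ZH",
)
CMU_VOWELS: frozenset[str] = frozenset(
    {"AA", "AE", "AH", "AO", "AW", "AY", "EH", "ER", "EY",
     "IH", "IY", "OW", "OY", "UH", "UW"}
)

MAX_LETTERS = 12
MAX_PHONEMES = 10


class LexiconError(ValueError):
    """Raised for malformed lexicon inputs or invariant violations."""


@dataclass(frozen=True)
class PhonemeInventory:
    """An ordered phoneme alphabet with a flagged vowel subset."""

    symbols: tuple[str, ...] = CMU_PHONEMES
    vowel_set: frozenset[str] = CMU_VOWELS

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise LexiconError("phoneme symbols must be unique")
        if not set(self.vowel_set) <= set(self.symbols):
            raise LexiconError("vowel_set must be a subset of symbols")

    def __len__(self) -> int:
        return len(self.symbols)

    def index(self, symbol: str) -> int:
        return self.symbols.index(symbol)

    def is_vowel(self, symbol: str) -> bool:
        return symbol in self.vowel_set

    def vowel_count(self, phonemes: Iterable[str]) -> int:
        return sum(1 for p in phonemes if p in self.vowel_set)

    def restrict(self, used: Iterable[str]) -> "PhonemeInventory":
        """Sub-inventory containing only `used` symbols, original order kept."""
        used_set = set(used)
        missing = used_set - set(self.symbols)
        if missing:
            raise LexiconError(f"unknown phonemes: {sorted(missing)}")
        syms = tuple(s for s in self.symbols if s in used_set)
        return PhonemeInventory(syms, frozenset(v for v in self.vowel_set if v in used_set))


@dataclass(frozen=True)
class LexiconEntry:
    """One word: spelling, pronunciation, and token frequency.

    Words are monosyllabic, operationalised as exactly one vowel phoneme
    (ARPAbet diphthongs are single symbols, so this is the syllable count).
    """

    spelling: str
    phonemes: tuple[str, ...]
    frequency: float

    def validate(self, inventory: PhonemeInventory) -> None:
        if not (1 <= len(self.spelling) <= MAX_LETTERS):
            raise LexiconError(f"{self.spelling!r}: spelling length out of range")
        if not self.spelling.isascii() or not self.spelling.isalpha() or not self.spelling.islower():
            raise LexiconError(f"{self.spelling!r}: spelling must be lowercase a-z")
        if not (1 <= len(self.phonemes) <= MAX_PHONEMES):
            raise LexiconError(f"{self.spelling!r}: phoneme count out of range")
        unknown = [p for p in self.phonemes if p not in inventory.symbols]
        if unknown:
            raise LexiconError(f"{self.spelling!r}: phonemes not in inventory: {unknown}")
        if inventory.vowel_count(self.phonemes) != 1:
            raise LexiconError(f"{self.spelling!r}: not monosyllabic")
        if not (self.frequency >= 0 and math.isfinite(self.frequency)):
            raise LexiconError(f"{self.spelling!r}: invalid frequency {self.frequency}")


@dataclass
class Lexicon:
    """A validated word list over a fixed phoneme inventory."""

    entries: list[LexiconEntry]
    inventory: PhonemeInventory = field(default_factory=PhonemeInventory)

    def __post_init__(self) -> None:
        spellings = [e.spelling for e in self.entries]
        if len(set(spellings)) != len(spellings):
            dupes = sorted({s for s in spellings if spellings.count(s) > 1})
            raise LexiconError(f"duplicate spellings: {dupes}")
        for e in self.entries:
            e.validate(self.inventory)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def spellings(self) -> list[str]:
        return [e.spelling for e in self.entries]

    def entry(self, spelling: str) -> LexiconEntry:
        for e in self.entries:
            if e.spelling == spelling:
                return e
        raise KeyError(spelling)


def _strip_stress(label: str) -> str:
    return label.rstrip("0123456789")


def read_pronunciation_dict(
    stream: TextIO | Iterable[str],
    inventory: PhonemeInventory | None = None,
) -> dict[str, tuple[str, ...]]:
    """Parse a CMU-dict style text stream into spelling -> phonemes.

    Lines look like ``BEST  B EH1 S T``; stress digits on vowels are
    stripped, ``;;;`` comment lines are ignored, and alternate-
    pronunciation entries such as ``BEST(2)`` are skipped so each word
    keeps its first-listed pronunciation.
    """
    inventory = inventory or PhonemeInventory()
    out: dict[str, tuple[str, ...]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.strip()
        if not line or line.startswith(";;;"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise LexiconError(f"line {lineno}: malformed entry {line!r}")
        word, labels = parts[0], parts[1:]
        if "(" in word:  # variant pronunciation, e.g. WORD(2)
            continue
        phonemes = tuple(_strip_stress(p) for p in labels)
        bad = [p for p in phonemes if p not in inventory.symbols]
        if bad:
            raise LexiconError(f"line {lineno}: phonemes not in inventory: {bad}")
        out[word.lower()] = phonemes
    return out


def read_frequency_table(stream: TextIO | Iterable[str]) -> dict[str, float]:
    """Parse a TSV with header ``word<TAB>frequency`` into a mapping."""
    out: dict[str, float] = {}
    lines = iter(stream)
    try:
        header = next(lines)
    except StopIteration:
        raise LexiconError("empty frequency table") from None
    cols = [c.strip().lower() for c in header.rstrip("\n").split("\t")]
    if cols[:2] != ["word", "frequency"]:
        raise LexiconError(f"unexpected header {cols!r}")
    for lineno, raw in enumerate(lines, start=2):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise LexiconError(f"line {lineno}: expected 2 columns")
        word = parts[0].strip().lower()
        try:
            freq = float(parts[1])
        except ValueError:
            raise LexiconError(f"line {lineno}: non-numeric frequency {parts[1]!r}") from None
        if freq < 0:
            raise LexiconError(f"line {lineno}: negative frequency for {word!r}")
        if word in out:
            raise LexiconError(f"line {lineno}: duplicate word {word!r}")
        out[word] = freq
    return out


def build_corpus(
    pronunciations: Mapping[str, tuple[str, ...]],
    frequencies: Mapping[str, float],
    min_freq: float = 10.0,
    stoplist: Iterable[str] = (),
    inventory: PhonemeInventory | None = None,
) -> Lexicon:
    """Intersect pronunciations and frequencies, keep monosyllables.

    A word survives when it appears in both sources, its frequency is
    strictly above `min_freq`, it has exactly one vowel phoneme, fits
    the 12-letter / 10-phoneme length bounds, and is not on the
    stoplist (used for excluding proper names).  Entries are returned
    in alphabetical order.
    """
    inventory = inventory or PhonemeInventory()
    stop = {w.lower() for w in stoplist}
    entries = []
    for word in sorted(pronunciations):
        if word in stop or word not in frequencies:
            continue
        freq = frequencies[word]
        if not freq > min_freq:
            continue
        phonemes = pronunciations[word]
        if len(word) > MAX_LETTERS or len(phonemes) > MAX_PHONEMES:
            continue
        if inventory.vowel_count(phonemes) != 1:
            continue
        if not (word.isascii() and word.isalpha() and word.islower()):
            continue
        entries.append(LexiconEntry(word, phonemes, freq))
    if not entries:
        raise LexiconError("no words survived corpus filtering")
    return Lexicon(entries, inventory)


def write_lexicon_tsv(lexicon: Lexicon, stream: TextIO) -> None:
    """Serialize as TSV: word, space-separated phonemes, frequency."""
    stream.write("word\tphonemes\tfrequency\n")
    for e in lexicon.entries:
        stream.write(f"{e.spelling}\t{' '.join(e.phonemes)}\t{e.frequency!r}\n")


def read_lexicon_tsv(
    stream: TextIO | Iterable[str],
    inventory: PhonemeInventory | None = None,
) -> Lexicon:
    inventory = inventory or PhonemeInventory()
    entries = []
    lines = iter(stream)
    header = next(lines).rstrip("\n").split("\t")
    if header != ["word", "phonemes", "frequency"]:
        raise LexiconError(f"unexpected lexicon header {header!r}")
    for raw in lines:
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        word, phon, freq = line.split("\t")
        entries.append(LexiconEntry(word, tuple(phon.split()), float(freq)))
    return Lexicon(entries, inventory)
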