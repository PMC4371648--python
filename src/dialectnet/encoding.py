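"""Vowel-centered localist slot codes for spellings and pronunciations.

Phonology uses 10 positional slots with one unit per phoneme symbol per
slot (39 symbols -> 390 units).  The vowel occupies slot 3, onset
consonants are right-aligned into slots 0-2 and coda consonants
left-aligned into slots 4-9, so the code is aligned on the syllable
nucleus rather than the word edge.  Orthography works the same way over
12 slots of 26 letter units (312 units), centered on the first vowel
letter: slot 4 holds that letter, up to 4 preceding letters fill slots
0-3 and up to 7 following letters fill slots 5-11.

Slot anchors are module constants; they were chosen so the longest
English monosyllabic onsets and codas fit the 10- and 12-slot layouts.
"""

from __future__ import annotations

import numpy as np

from .lexicon import PhonemeInventory

__all__ = [
    "ILL_FORMED",
    "EncodingError",
    "PHON_SLOTS",
    "PHON_VOWEL_SLOT",
    "ORTH_SLOTS",
    "ORTH_VOWEL_SLOT",
    "LETTERS",
    "encode_phonology",
    "decode_phonology",
    "encode_orthography",
    "orth_vowel_position",
    "n_phon_units",
    "n_orth_units",
]

PHON_SLOTS = 10
PHON_VOWEL_SLOT = 3
ORTH_SLOTS = 12
ORTH_VOWEL_SLOT = 4
LETTERS = "abcdefghijklmnopqrstuvwxyz"

#: Sentinel decode result: the activation pattern names no legal string.
ILL_FORMED = "ILL_FORMED"


class EncodingError(ValueError):
    """Raised when a string does not fit the slot scheme."""


def n_phon_units(inventory: PhonemeInventory) -> int:
    return PHON_SLOTS * len(inventory)


def n_orth_units() -> int:
    return ORTH_SLOTS * len(LETTERS)


def encode_phonology(
    phonemes: tuple[str, ...], inventory: PhonemeInventory
) -> np.ndarray:
    """Binary slot pattern for a monosyllabic phoneme string.

    Exactly one unit is active per occupied slot; unoccupied slots are
    all-zero, so the number of active units equals the number of
    phonemes.
    """
    n = len(inventory)
    vowels = [i for i, p in enumerate(phonemes) if inventory.is_vowel(p)]
    if len(vowels) != 1:
        raise EncodingError(f"{phonemes!r}: need exactly one vowel phoneme")
    v = vowels[0]
    onset, coda = phonemes[:v], phonemes[v + 1:]
    if len(onset) > PHON_VOWEL_SLOT:
        raise EncodingError(f"{phonemes!r}: onset exceeds {PHON_VOWEL_SLOT} slots")
    if len(coda) > PHON_SLOTS - PHON_VOWEL_SLOT - 1:
        raise EncodingError(f"{phonemes!r}: coda exceeds {PHON_SLOTS - PHON_VOWEL_SLOT - 1} slots")
    pattern = np.zeros(PHON_SLOTS * n)
    for offset, p in enumerate(reversed(onset), start=1):
        pattern[(PHON_VOWEL_SLOT - offset) * n + inventory.index(p)] = 1.0
    pattern[PHON_VOWEL_SLOT * n + inventory.index(phonemes[v])] = 1.0
    for offset, p in enumerate(coda, start=1):
        pattern[(PHON_VOWEL_SLOT + offset) * n + inventory.index(p)] = 1.0
    return pattern


def decode_phonology(
    activations: np.ndarray,
    inventory: PhonemeInventory,
    hi: float = 0.75,
    lo: float = 0.25,
) -> tuple[str, ...] | str:
    """Read a phoneme string off an activation vector, or ILL_FORMED.

    A slot contributes a phoneme iff exactly one of its units is above
    `hi` and every other unit in the slot is below `lo`; an empty slot
    must have all units below `lo`.  Any unit in the indeterminate band
    [lo, hi] anywhere, or two high units in one slot, makes the whole
    pattern ill-formed.  The scoring covers all units including empty
    slots.
    """
    if not hi > lo:
        raise ValueError("need hi > lo")
    n = len(inventory)
    a = np.asarray(activations).reshape(PHON_SLOTS, n)
    phonemes: list[str] = []
    for slot in range(PHON_SLOTS):
        row = a[slot]
        high = np.flatnonzero(row > hi)
        if len(high) == 0:
            if np.any(row >= lo):
                return ILL_FORMED
            continue
        if len(high) > 1:
            return ILL_FORMED
        rest = np.delete(row, high[0])
        if np.any(rest >= lo):
            return ILL_FORMED
        phonemes.append(inventory.symbols[high[0]])
    if not phonemes:
        return ILL_FORMED
    return tuple(phonemes)


def orth_vowel_position(spelling: str) -> int:
    """Index of the centering letter: first a/e/i/o/u, or y non-initially."""
    for i, ch in enumerate(spelling):
        if ch in "aeiou" or (ch == "y" and i > 0):
            return i
    raise EncodingError(f"{spelling!r}: no vowel letter")


def encode_orthography(spelling: str) -> np.ndarray:
    """Binary slot pattern for a lowercase spelling, first vowel at slot 4."""
    if not spelling or not spelling.isascii() or not spelling.isalpha() or not spelling.islower():
        raise EncodingError(f"{spelling!r}: spelling must be lowercase a-z")
    v = orth_vowel_position(spelling)
    pre, post = spelling[:v], spelling[v + 1:]
    if len(pre) > ORTH_VOWEL_SLOT:
        raise EncodingError(f"{spelling!r}: more than {ORTH_VOWEL_SLOT} pre-vowel letters")
    if len(post) > ORTH_SLOTS - ORTH_VOWEL_SLOT - 1:
        raise EncodingError(f"{spelling!r}: more than {ORTH_SLOTS - ORTH_VOWEL_SLOT - 1} post-vowel letters")
    n = len(LETTERS)
    pattern = np.zeros(ORTH_SLOTS * n)
    for offset, ch in enumerate(reversed(pre), start=1):
        pattern[(ORTH_VOWEL_SLOT - offset) * n + LETTERS.index(ch)] = 1.0
    pattern[ORTH_VOWEL_SLOT * n + LETTERS.index(spelling[v])] = 1.0
    for offset, ch in enumerate(post, start=1):
        pattern[(ORTH_VOWEL_SLOT + offset) * n + LETTERS.index(ch)] = 1.0
    return pattern
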