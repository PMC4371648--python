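"""Packaged example data: a toy CMU-format lexicon for worked examples."""

from __future__ import annotations

import io
from importlib import resources

from .lexicon import Lexicon, build_corpus, read_frequency_table, read_pronunciation_dict
from .rules import DEFAULT_RULESET, DialectCorpus, build_aae_corpus

__all__ = ["load_toy_lexicon", "load_toy_dialect_corpus"]


def _read(name: str) -> io.StringIO:
    return io.StringIO(resources.files("dialectnet.data").joinpath(name).read_text())


def load_toy_lexicon() -> Lexicon:
    """Thirteen hand-picked words with CMU pronunciations and frequencies."""
    pron = read_pronunciation_dict(_read("toy_lexicon.dict"))
    freq = read_frequency_table(_read("toy_frequencies.tsv"))
    return build_corpus(pron, freq, min_freq=10.0)


def load_toy_dialect_corpus(seed: int = 0) -> DialectCorpus:
    """AAE corpus derived from the toy lexicon with the default ruleset."""
    return build_aae_corpus(load_toy_lexicon(), DEFAULT_RULESET, seed=seed)
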