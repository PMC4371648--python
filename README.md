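# dialectnet

Connectionist simulations of how dialect differences affect learning to
decode print.

Many African American children speak African American English (AAE), a
dialect whose phonology differs in systematic ways from the Mainstream
American English (MAE) emphasized in school — for example, word-final
consonant-cluster reduction gives BEST → /bɛs/ and TOLD → /tol/.  For a
child who knows both forms, one spelling maps to two pronunciations,
making the already inconsistent English spelling–sound system more
ambiguous for exactly those *Contrastive* words.  `dialectnet` provides
the modeling machinery to study this: it builds paired MAE/AAE training
corpora with a configurable phonological rule engine, trains a
recurrent attractor network to map spellings onto pronunciations under
Match, Mismatch, and Bi-dialectal regimes, and localizes the resulting
learning differences by word class.

The package is for computational psycholinguists and reading
researchers who want a runnable, testable implementation of the
triangle-model style of decoding simulation with dialect variation as a
first-class experimental factor.

## The model

A word's pronunciation is a localist slot code: 10 vowel-centered slots
× one unit per phoneme (39 stress-stripped ARPAbet phonemes → 390
units); spellings use 12 slots × 26 letters (312 units) centered on the
first vowel letter.  The network is

    orthography (312) → hidden (50) → phonology (n×10)
                                        ↑↓ cleanup (20), phonology↔phonology

with two optional dialect context units feeding the hidden and
phonological layers.  The interconnected phonological units and cleanup
bank form an attractor: activation settles over discrete synchronous
steps toward learned pronunciations.  Training minimizes cross-entropy
between the settled output and the target over the final settling
steps, scaled by √(word frequency); weights are updated after every
trial by backpropagation through the unrolled settling dynamics.

Learning has two phases.  In the **speech phase** the model learns to
maintain clamped pronunciations (spoken vocabulary, trained to a 95%
criterion).  In the **reading phase**, reading trials (spelling →
pronunciation, at 1/10 the speech error weight) are interleaved with
continued speech trials.  Conditions differ in which dialect supplies
the targets: `mae_match`, `aae_match`, `mismatch` (AAE speech, MAE
reading), and three `bidialectal_*` conditions in which speech training
presents the AAE form but demands either dialect's form as output, with
context units never / always / late signalling the intended dialect.

Performance is scored with the standard 0.75/0.25 criterion (all target
units above 0.75, all others below 0.25), and word difficulty by
unscaled cross-entropy, compared across Contrastive and Non-contrastive
words matched on log frequency, length, and initial phoneme.

## Worked example

Build a 300-word synthetic lexicon (Zipf frequencies, ~51% of words
eligible for an AAE rule), derive its AAE corpus, and train the
Mismatch condition for 200 reading epochs:

```python
from dialectnet import GenSpec, generate_lexicon, build_aae_corpus
from dialectnet.training import run_condition
from dialectnet.evaluation import evaluate_reading

lexicon = generate_lexicon(GenSpec(n_words=300, seed=1))
corpus = build_aae_corpus(lexicon, seed=1)
print(f"{len(corpus)} words, {corpus.contrastive_fraction:.0%} contrastive")

result = run_condition(corpus, "mismatch", seed=1, reading_epochs=200)
report = evaluate_reading(result["network"], corpus, "mae")
print(f"overall accuracy      {report.overall_accuracy:.1f}%")
print(f"  contrastive         {report.accuracy_contrastive:.1f}%")
print(f"  non-contrastive     {report.accuracy_non_contrastive:.1f}%")
print(f"mean CE contrastive   {report.mean_ce_contrastive:.2f}")
print(f"mean CE non-contr.    {report.mean_ce_non_contrastive:.2f}")
```

```
300 words, 51% contrastive
overall accuracy      79.0%
  contrastive         76.5%
  non-contrastive     81.6%
mean CE contrastive   0.95
mean CE non-contr.    0.91
```

The Mismatch model's deficit sits on the Contrastive words — the ones
whose speech-phase (AAE) pronunciation conflicts with the required MAE
reading target — while Non-contrastive words track the Match
conditions; averaged over seeds the deficit also shows in the residual
cross-entropy.  The same pipeline drives the rule engine directly:

```python
from dialectnet import load_toy_dialect_corpus, homophone_report
corpus = load_toy_dialect_corpus()
print(corpus.word("best").aae_phonemes)   # ('B', 'EH', 'S')
print(homophone_report(corpus))           # [{'cold', 'coal'}] — COLD collapses onto COAL
```

A CLI mirrors the library (`dialectnet build-corpus | train | evaluate
| suite`); see `dialectnet --help`.

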