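# Methods

`dialectnet` simulates how learning to *decode* — mapping printed words
onto pronunciations — is affected when a child's home dialect (African
American English, AAE) differs from the dialect of reading instruction
(Mainstream American English, MAE).  The package contains a full
simulation pipeline: corpus construction, a dialect rule engine, slot
encoders, a recurrent attractor network trained by backpropagation
through time, training protocols for six named conditions, and scoring
machinery.  This note records the model, its parameters, and the design
choices that were genuinely open.

## Corpora

A lexicon is a set of monosyllabic words (exactly one vowel phoneme;
ARPAbet diphthongs are single symbols) with spellings of 1–12 lowercase
letters, pronunciations of 1–10 phonemes drawn from the 39 stress-
stripped CMU phonemes, and token frequencies on the scale of
second-grade print-exposure norms.  Corpus construction keeps words
present in both the pronunciation and the frequency source, with
frequency strictly above 10, and excludes words on a user-supplied
stoplist (intended for proper names; the default list is empty because
no published list exists).

The AAE corpus is derived from the MAE corpus by a rule engine.  The
default ruleset is a reconstruction of five widely documented AAE
phonological features — final devoicing of a post-vocalic voiced stop,
onset and coda interdental substitution, final consonant-cluster
reduction (with velar-nasal+stop codas and a final /s z/ after a
cluster exempt), and postvocalic /r/ deletion.  Every rule is a plug-in
(`PhonRule`: a context predicate plus a rewrite), so the set is fully
configurable.  When several rules match a word, exactly one is chosen
uniformly at random (seeded); words changed by a rule are *Contrastive*,
the rest *Non-contrastive*.  On a real-scale corpus roughly half the
words are eligible for at least one rule.

## Representations

Phonology: 10 positional slots × one unit per phoneme, vowel-centered —
the vowel occupies slot 3, onset consonants are right-aligned into
slots 0–2, coda consonants left-aligned into slots 4–9.  Orthography:
12 slots × 26 letters, centered on the first vowel letter (a/e/i/o/u,
or y when not word-initial) at slot 4.  With the full CMU inventory
this gives 390 phonological units and 312 orthographic units.  The
slot anchors are this package's choice; they fit the longest English
monosyllabic onsets (3 phonemes / 4 letters) and codas (6 phonemes /
7 letters) into the 10- and 12-slot layouts.

A phonological output is scored by the 0.75/0.25 criterion: a slot
contributes a phoneme iff exactly one of its units exceeds 0.75 and all
its other units are below 0.25; empty slots must be entirely below
0.25.  The criterion is applied over *all* units, including empty
slots; any unit in the indeterminate band makes the pattern ill-formed.
Whether the original scoring covered empty slots is not recoverable;
covering them is the stricter reading and is stated here as a decision.

## Network and learning

Architecture: orthography (312) → hidden (50) → phonology, with
phonology↔phonology recurrence (zero diagonal), phonology↔cleanup (20)
recurrence, and two context units feeding both the hidden and
phonological layers.  The fan-out of the context units is a
free choice; feeding both layers is the default and is configurable.

Settling is discrete-time and synchronous with logistic units, standing
in for the continuous-time dynamics of the antecedent models (whose
integration constants are not available).  Per step,

    c_t = σ(W_pc' p_{t-1} + b_c)
    p_t = σ(W_hp' h + W_pp' p_{t-1} + W_cp' c_{t-1} + W_xp' x + b_p)

with the hidden layer h computed once per trial (it receives no
recurrent input) and silenced entirely on trials without an
orthographic input.  Silencing is a design choice: it makes spoken-word
learning a property of the phonological attractor alone, so the
orthography→phonology route is shaped only by reading.  (The
alternative — letting bias-driven hidden activity run on speech trials
— routes high-weight speech error through the shared reading pathway
every epoch and measurably degrades learning in all conditions.)  On
speech trials the pronunciation is clamped on the phonological layer
for the first `clamp_steps` steps.  Free units start at the resting
activation σ(bias_init).

The loss is cross-entropy summed over the final `target_steps` steps
and all phonological units, activations clipped to [1e-7, 1-1e-7]
inside the logs, multiplied by the trial's error scale.  Training uses
an *error radius* (`error_margin`, 0.1 in the routine simulations), a
standard device in attractor models of word reading: an output unit
within 0.1 of its target contributes neither loss nor gradient.
Without it, binary targets drive the recurrent weights without bound —
attractors deepen until the settling dynamics pass through a chaotic
regime and accuracy intermittently collapses, which made end-of-
training performance erratic across seeds.  With the radius, mastered
words quiesce, the weights stop growing, and runs are stable; words
with genuinely conflicting targets (Contrastive words in the Mismatch
and Bi-dialectal regimes) never quiesce, which is exactly the
difficulty signal the evaluation reads out.  Gradients are computed by
backpropagation through the unrolled settling steps; one gradient-
descent update is applied per trial (online learning, no momentum).
With margin 0 the analytic gradients agree with central finite
differences to better than 1e-4 relative error (tested).

Numerical defaults (package choices, tuned on the toy fixtures):
settle/clamp/target = 12/6/3 steps in `NetConfig`; the routine
simulations use a shortened 8/4/2 schedule (the qualitative behaviour
is unchanged and runs are ~40% cheaper).  Weights initialise uniformly
in ±0.1, biases at −2 so free units rest near 0.12, below the decode
floor.  Learning rate 0.1 for few-hundred-word corpora.  `delta_clip`
(off by default) can additionally cap the joint norm of a trial's BPTT
deltas as a blowup guard.

## Training protocols

Error scaling: cross-entropy is scaled by sqrt(frequency), normalised
by the corpus mean of sqrt(frequency) — a global constant that makes
the learning rate independent of the frequency scale while preserving
relative word weighting — and capped at 3 (the cap compresses only the
few highest-frequency words of a Zipf-distributed corpus, whose
outsized online updates otherwise destabilise training; frequency
compression of this kind is routine in connectionist reading models).
Reading trials use exactly 1/10 of the speech scale, reflecting that
beginning readers hear words far more often than they read them.

**Speech phase.**  Each word once per epoch in seeded random order:
clamp the pronunciation, free-run, target the same pronunciation.  The
phase ends at the first epoch whose accuracy reaches the criterion
(95% by default), or at an epoch cap.

**Reading phase.**  Each epoch interleaves, in one seeded shuffle, one
reading trial per word (spelling in, reading-dialect pronunciation out)
and one speech trial per word (as in the speech phase).  The
interleaving ratio (1:1) is a package choice.

**Conditions.**  `mae_match` and `aae_match` use one dialect
throughout; `mismatch` trains speech on AAE and reading on MAE.  The
three bi-dialectal conditions train speech on *both* dialects: the
clamped input is always the AAE form and the target is either the AAE
form (maintenance) or the MAE form (conversion), drawn 50/50 per epoch
so each variant carries half the word's frequency — the error scale is
sqrt(f/2), i.e. halving happens inside the square root (the alternative
reading sqrt(f)/2 is a configurable switch).  Because the same input must yield different
outputs, the task is ambiguous without context.  The bi-dialectal
speech phase is capped at the epoch count of the same-seed AAE speech
phase (matched training), and typically does not reach the criterion.
Context units are never used in the speech phase.  In the reading
phase, the Early condition lights them from epoch 0, the Late condition
from the halfway epoch, and the No-Context condition never: reading
trials always light the MAE unit; interleaved speech trials light the
unit of the target dialect (MAE for Non-contrastive words).  Whether
the original Late condition cued Non-contrastive speech trials before
the halfway point is not recoverable from the text; this implementation
treats Early and Late identically except for onset.

**Evaluation.**  Reading accuracy uses the 0.75/0.25 criterion on the
final settling step, with the MAE context unit lit iff the condition's
schedule is active at that epoch.  The word-difficulty index is the
unscaled residual cross-entropy of the training objective — CE beyond
the error radius — which is near zero for mastered words and remains
elevated exactly where targets conflict, and is frequency-unweighted so
word classes are comparable.  Matched Contrastive/Non-contrastive
test pairs are built greedily (seeded order): same initial MAE phoneme,
identical letter count, |Δlog10 frequency| ≤ 0.3; all tolerances
configurable.  End-of-training performance is summarised as the mean of
the last three evaluation points of a run — a smoothed read-out under
online learning — averaged across seeds.

## Synthetic lexicons

Because the real training corpus is derived from licensed frequency
norms, the test suite and routine simulations run on synthetic lexicons
that emulate its statistical structure: onset+vowel+coda forms over a
26-phoneme sub-inventory (22 onsets, 8 vowels, 24 codas, including
rule-eligible codas and the exempt velar-nasal clusters), spellings
derived from a per-phoneme grapheme map with consistency parameter c
(default 0.85: 15% of phoneme tokens take an alternate spelling,
injecting English-like spelling–sound inconsistency), Zipf-distributed
frequencies (exponent 1.0, lognormal jitter sd 0.15, floored just above
the inclusion threshold), and a quota-enforced fraction of rule-eligible
words (default 0.51, the real corpus's design point).  The inventories
are sized so a 50-hidden-unit network learns a 300-word lexicon in
minutes; they are a test-scale idealisation of English phonotactics,
not a model of it.

What the synthetic lexicon does *not* emulate: real English phonotactic
frequencies, positional grapheme context (silent e, digraph
conditioning), morphology, or the correlation between frequency and
phonological form.  Passing tests on it show that the *mechanisms*
(ambiguity of Contrastive mappings, attractor interference, context
cueing) behave as described, not that the model quantitatively fits
English.

## Study scale

The routine study trains a 300-word synthetic lexicon (51%
rule-eligible) under all six conditions with three seeds and 200
reading epochs — sizes chosen so the whole 18-run study completes in
minutes on one core while preserving the qualitative contrasts; a
full-scale design (a ~1700-word real lexicon, 1000 epochs) is reachable with
the same code by supplying a real lexicon and raising the epoch count.

## Known limitations

- No semantic pathway, morphology, or stress; monosyllables only.
- Discrete synchronous settling; no continuous-time integration.
- The default AAE ruleset is a reconstruction; rule identities beyond
  the two exemplified in print (interdental substitution, cluster
  reduction) are plausible but not authoritative, and are configurable.
- Accuracy under online learning fluctuates between epochs; single-
  epoch snapshots are noisy, which is why end-of-training values are
  smoothed over the last three evaluations.
- The behavioral analyses (naming latencies, mixed-effects regressions)
  are out of scope; only the stimulus table's descriptive statistics
  are packaged.
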