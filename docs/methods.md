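# Methods

## Detection model

Detection is dictionary-based at the speaker-turn level. A keyword library
is a finite set of literal lowercase terms (single words or multi-word
phrases), each assigned one or more nonexclusive PRO-CTCAE symptom
categories, plus a set of exclusion phrases. Turn text is normalized by
lowercasing and straightening Unicode quotes/apostrophes (both
length-preserving, so character offsets refer to the original text), then
tokenized into maximal runs of letters/digits with internal apostrophes and
hyphens; spans are 0-based half-open. A single-word term matches any equal
token; a multi-word phrase matches a contiguous equal token sequence.
Matching is strictly at token boundaries — "red" cannot fire inside
"bothered" — and terms are never treated as regular expressions, which
keeps the library auditable by clinicians.

Exclusions are contextual suppressors, not term deletions: a candidate
match is suppressed iff its character span lies fully inside an occurrence
of an exclusion phrase in the same turn. This supports the canonical case
of a physical-exam instruction ("take a few deep breaths") silencing
breath-family keywords without removing them from the library. All
surviving occurrences are reported (overlaps included; detection is binary
at the turn level, so multiplicity is informational only). Context never
crosses turn boundaries: responses like "yes" or "seven and three quarters"
to a symptom question are undetectable by design — an accepted limitation
of rule-based methods.

### Morphology and variants

Plural and inflected forms are separate explicit entries ("deep breath" /
"deep breaths"), not stems. This trades recall on unseen inflections for
exact auditability of what the library matches.

## Gold standards

Coders score each turn 0–3 for symptom relevance. The **broad** standard is
positive iff the mean of available scores is ≥ 2.0 (closed bound, tested at
the boundary); turns scored by a single coder are allowed. The
**PRO-CTCAE-focused** standard overlays manual per-turn boolean overrides
on the broad labels; overrides live in a sidecar file keyed by
(conversation, turn) so the focused standard is reproducible. The override
operation is idempotent and rejects unknown keys.

Reliability: Cohen's κ = (p_o − p_e)/(1 − p_e) per coder pair on the turns
both scored, averaged across pairs, or Fleiss' κ on turns scored by all
coders. Both are computed from the closed forms (and cross-checked in tests
against scikit-learn and statsmodels); κ is reported as NaN with a warning
when chance agreement is 1. The kappa kind and the binarization threshold
(default 2, matching the broad standard) are explicit parameters, since a
single reported κ value rarely pins down either choice.

## Evaluation

Confusion counts are computed over an exactly shared turn set (a mismatch
is an error, not a silent intersection). The five metrics follow the stated
formulas; any metric with a zero denominator is an explicit `None`, never
0, because strata can be tiny (a single conversation) and a silent zero
would bias comparisons. Display rounding is half-up to 2 decimals; raw
values are retained. Stratification partitions turns by a
conversation-level metadata key with a "Missing" stratum, so per-stratum
counts always sum to the overall counts; stratum assignment is at the
conversation level because attributes like self-reported race belong to the
patient, not the turn.

Review sampling draws misclassified (FP ∪ FN) and true-positive turns with
a seeded generator, allocating round-robin across dataset labels so
proportions are as even as the pools allow, with an optional per-patient
cap; infeasible requests fail naming the binding constraint.

## Library curation loop

Candidate mining enumerates all n-grams (default n ≤ 3, covering observed
multi-word symptom phrases) over the turns the chosen gold standard marks
positive, with a minimum-frequency threshold (default 1, i.e. every phrase
is reviewable) and a small function-word stoplist applied to single-word
candidates only. Inclusion/exclusion decisions are recorded in an
append-only triage log with rationale and decider; replaying the log over a
library is idempotent and yields a diff containing exactly the logged
inclusions. Automated inclusion rules are deliberately absent — triage is
human work; the module only makes it reproducible.

Library versions are compared with a diff (added, removed, recategorized,
exclusions added/removed) satisfying `apply(a, diff(a, b)) == b` and
`|B| = |A| + |added| − |removed|`, property-tested on randomized library
pairs.

## Synthetic corpus generator

The generator emulates the turn mix of transcribed outpatient oncology
encounters with template text: filler sentences, symptom templates with a
slotted lexicon term (mechanism `lexical`), colloquial paraphrases
containing no lexicon term (`colloquial`), and decoy clauses that
superficially resemble symptom talk (`decoy`). Defaults: 12% of turns are
symptom-positive (matching the positive fraction of annotated encounter
corpora of this kind), 45% of positives are colloquial with 33% of those
still framework-relevant (so the focused standard lifts sensitivity from
≈ 0.55 toward ≈ 0.8, the ordering observed between broad and focused
standards on real data), and 15% of negatives carry a decoy. Conversations
are grouped under patients (1–3 each); dataset label and stratum are
patient attributes, with optional per-stratum decoy rates for stratified
testing. Coder scores are 3/0 for positive/negative turns, perturbed ±1
with probability ε ∈ [0, 0.5] truncated to [0, 3]; with ε = 0 the broad
standard recovers the planted truth exactly. The generated override sidecar
corrects annotator noise and downgrades non-relevant colloquial turns, so
after overrides the focused labels equal the planted focused truth.

With ε = 0 the model has a closed form: sensitivity = 1 − c (lexical
positives always match, colloquial never), false positives arise only from
decoys overlapping the lexicon (per-negative-turn rate a·q, where q is the
decoy hit fraction measured by running the matcher on the decoy clauses),
hence precision = 1 and specificity = 1 under the shipped decoy list, which
is disjoint from the seed lexicon. The generator validates at run time that
fillers and paraphrases contain no lexicon term and that slotted terms
match their rendering.

What the generator does **not** model: dialogue coherence, cross-turn
symptom discussion, misspellings and transcription noise, and realistic
false-positive ambiguity (mood language used conversationally) unless the
user supplies decoys overlapping their library. Passing end-to-end tests
therefore demonstrates correctness of the machinery under the generative
model, not field performance on real transcripts.

## Numerical and I/O choices

- Seeds: every stochastic operation takes an explicit integer seed feeding
  `numpy.random.default_rng`; outputs carry provenance headers (tool
  version, library version label, seed).
- Duplicate library terms on load collapse to one entry with the union of
  categories (warned), since categories are nonexclusive.
- Category vocabulary is configurable; the shipped default is the ten
  body-system groupings used for PRO-CTCAE curation (pain, GI, sleep/wake,
  neurological, cutaneous, mood/anxiety, respiratory, oral, sexual, other).
- Tie-breaks: candidate lists sort by descending frequency then
  lexicographically; matches sort by span then term; diffs sort terms
  lexicographically — all outputs are byte-stable under a fixed seed.
- Degenerate inputs: empty turns detect nothing; an empty library, an
  emptied filter result, a zero-turn evaluation and an over-sized review
  request are errors, not silent empties; an empty corpus directory is a
  warning.

## Problem sizes

The default test suite exercises the matcher-oracle equivalence on 1200+
randomized library/sequence pairs, the metric identities on 10⁴ random
count vectors, and the end-to-end recovery on a generated corpus of ≈ 6000
turns — sizes at which binomial sampling error is small relative to the
3-standard-error acceptance bands while the whole suite stays fast.
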