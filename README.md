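# symtalk

Rule-based detection of **symptom talk** in transcribed clinical
conversations.

Patients with advanced cancer carry a heavy symptom burden, yet much of what
they say about symptoms in the clinic is never documented. `symtalk`
implements a transparent, auditable baseline for finding that talk: a
curated **keyword library** grounded in the PRO-CTCAE framework (the
Patient-Reported Outcome version of the Common Terminology Criteria for
Adverse Events, covering ~80 clinically relevant cancer symptoms) is applied
at the level of the **speaker turn** — an uninterrupted span of speech — in
transcripts of oncology encounters. It is intended for clinical-NLP
researchers who need a reproducible dictionary baseline, a lexicon-curation
workbench, or a harness for evaluating more advanced models.

## What it computes

A turn is **detected** iff it contains at least one library term — a single
word matching a token, or a multi-word phrase matching a contiguous token
sequence, case-insensitively, at token boundaries (never substrings) —
unless every such match lies inside an occurrence of an **exclusion
pattern** (e.g. exam-context "deep breaths"). No other rules are applied.

Detection is scored against two turn-level gold standards built from ordinal
coder annotations (0–3 scale): the **broad** standard, positive iff the mean
coder score ≥ 2; and the **PRO-CTCAE-focused** standard, the broad labels
manually overridden to reflect relevance to the framework the library
targets. From the confusion counts TP/FP/TN/FN:

- sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
  precision = TP/(TP+FP), accuracy = (TP+TN)/total,
  F1 = 2TP/(2TP+FP+FN),

optionally stratified by conversation metadata (e.g. patient self-reported
race). Inter-rater reliability is available as Cohen's κ (pairwise mean) or
Fleiss' κ on binarized labels. Supporting machinery covers library
versioning and diffs, keyword-in-context (KWIC) concordances, n-gram
candidate mining with an append-only triage log, seeded sampling of
misclassified turns for qualitative review, and a synthetic-conversation
generator with planted ground truth.

## Worked example

The package ships a small seed lexicon (64 terms, 2 exclusions) as a working
default; a full curated library is loaded the same way from a CSV or YAML
file.

```python
import symtalk as st

lex = st.seed_lexicon()
turn = st.Turn(0, "clinician", "Do you need any more Ativan?")
result = st.detect_turn(st.normalize_and_tokenize(turn), lex)
print(result.detected, result.matched_terms, sorted(result.categories))
# True ['ativan'] ['mood/anxiety']

# exclusion: exam instruction, not a symptom description
turn = st.Turn(1, "clinician", "Take a few deep breaths for me")
print(st.detect_turn(st.normalize_and_tokenize(turn), lex).detected)
# False

# evaluate on a synthetic corpus with planted truth
cfg = st.GeneratorConfig(n_conversations=10, seed=1)
corpus = st.generate(cfg, lex)
detections = st.detect_corpus(corpus.conversations, lex)
report = st.evaluate(detections, corpus.broad_gold(), "broad")
print(report.counts, report.metrics.rounded())
# ConfusionCounts(tp=41, fp=0, tn=521, fn=31)
# {'sensitivity': 0.57, 'specificity': 1.0, 'precision': 1.0,
#  'accuracy': 0.95, 'f1': 0.73}
```

The sensitivity of 0.57 is by construction: in this configuration 45% of
symptom-positive turns use colloquial paraphrases that name no lexicon term
("things will just run through me"), which a dictionary method necessarily
misses; precision is 1.0 because the default decoy phrases are disjoint from
the lexicon. Applying the PRO-CTCAE-focused overrides (which downgrade the
non-framework-relevant share of that colloquial talk) raises F1 — the same
qualitative gap seen between the two gold standards on real transcripts.

The same operations are available from a CLI:

```sh
symtalk simulate --out demo --n-conversations 10 --seed 1
symtalk detect --corpus demo/transcripts --library <library.csv> --out detections.csv
symtalk evaluate --corpus demo/transcripts --library <library.csv> \
    --annotations demo/annotations.csv --overrides demo/overrides.csv \
    --standard proctcae --stratify-by race --out report.yaml
symtalk kwic --corpus demo/transcripts --term worry --window 7
symtalk mine --corpus demo/transcripts --annotations demo/annotations.csv \
    --library <library.csv> --min-freq 2 --out candidates.csv
```

## Limitations

A dictionary method detects only pre-defined surface forms: conversational
symptom discussion spread over multiple turns, pain ratings ("seven and
three quarters"), and novel colloquialisms are missed, and ambiguous mood
language ("don't worry") can mislead it. See `docs/methods.md` for the
model, parameter and design details.
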