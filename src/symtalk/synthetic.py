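"""Synthetic conversation generator with planted ground truth.

Real oncology transcripts cannot be redistributed, so every pipeline stage
is exercised on generated conversations whose per-turn truth is known by
construction.  Turn text is template-based — filler sentences with slotted
phrases — which is sufficient for exercising token-boundary matching,
exclusion handling, gold-standard construction and evaluation; it makes no
attempt at dialogue coherence.

Each turn is one of four mechanisms:

* ``lexical`` — symptom-positive; a seed-lexicon term slotted into a symptom
  template, so the keyword matcher always finds it;
* ``colloquial`` — symptom-positive; a paraphrase that names no lexicon term
  (e.g. "things will just run through" for diarrhea), so the matcher always
  misses it.  A configurable fraction of these count as relevant under the
  PRO-CTCAE-focused standard; the rest are downgraded by the generated
  override sidecar, reproducing the gap between the two gold standards;
* ``decoy`` — negative; contains language that superficially resembles
  symptom talk (exam-context "deep breaths", reassurance idioms).  The
  shipped decoy list is disjoint from the seed lexicon; supplying decoys
  that overlap a library models false positives;
* ``filler`` — negative small talk and logistics.

Coder scores are 3 for positive and 0 for negative turns, each perturbed by
±1 with probability ``coder_noise`` (truncated to 0–3); with zero noise the
broad gold standard binarizes back to the planted truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation import CoderScore, TurnKey, build_broad_gold
from .evaluation import MetricSet
from .library import KeywordLibrary
from .matching import _CompiledLibrary, detect_turn
from .transcripts import Conversation, Turn, normalize_and_tokenize


class GenerationError(ValueError):
    pass


#: Negative small talk / logistics; must contain no seed-lexicon term.
FILLER_SENTENCES = (
    "We should schedule the next visit before you leave.",
    "The parking garage was completely full again this morning.",
    "My daughter is coming to stay with us next weekend.",
    "Let me pull up your chart here for a second.",
    "The insurance paperwork finally went through last week.",
    "We watched the game last night with the neighbors.",
    "Thanks so much for coming in today.",
    "The lab is just down the hall on the left.",
    "I will send the summary to your primary doctor.",
    "Traffic on the bridge was unbelievable today.",
)

#: Symptom-positive templates; ``{term}`` is replaced by a lexicon term.
SYMPTOM_TEMPLATES = (
    "I have been having a lot of {term} lately.",
    "The {term} has been really bad this past week.",
    "Any {term} since the last visit?",
    "She keeps mentioning the {term} in the evenings.",
    "Is the {term} better or worse than last month?",
    "Honestly the {term} is what bothers me most.",
)

#: Colloquial symptom paraphrases (surface, symptom category): positive turns
#: that contain no seed-lexicon term, modelling newly encountered language.
DEFAULT_PARAPHRASES = (
    ("things will just run through me after i eat", "GI"),
    ("i can barely keep any food down these days", "GI"),
    ("i toss and turn most of the night", "sleep/wake"),
    ("my head feels like it is in a fog all day", "neurological"),
    ("i get winded just walking out to the mailbox", "respiratory"),
    ("everything i eat tastes like metal now", "oral"),
    ("my hands and feet feel like pins are in them", "neurological"),
    ("i just feel on edge about every little thing", "mood/anxiety"),
)

#: Negative decoy clauses resembling symptom language; the default list is
#: disjoint from the seed lexicon (so it plants no false positives).
DEFAULT_DECOYS = (
    "take a few deep breaths for me",
    "no need to fret about the schedule",
    "take your time getting up from the chair",
    "that color looks wonderful on you",
    "we will run through the plan together",
)


@dataclass
class GeneratorConfig:
    """Knobs for the generator; defaults emulate the turn mix of transcribed
    outpatient oncology encounters (roughly one turn in eight touches
    symptoms, about half of symptom talk phrased in words a keyword library
    would not carry, and a third of that still being framework-relevant)."""

    n_conversations: int = 40
    turns_per_conversation: tuple[int, int] = (30, 90)
    symptom_prevalence: float = 0.12
    ambiguity_rate: float = 0.15
    colloquial_rate: float = 0.45
    colloquial_relevant_fraction: float = 0.33
    coder_noise: float = 0.0
    n_coders: int = 1
    seed: int = 0
    dataset_split: dict[str, float] = field(
        default_factory=lambda: {"validation": 0.5, "test": 0.5}
    )
    strata: dict[str, float] = field(
        default_factory=lambda: {
            "White": 0.55,
            "Black/African American": 0.25,
            "Other": 0.20,
        }
    )
    stratum_ambiguity: dict[str, float] | None = None
    stratum_key: str = "race"

    def validate(self) -> None:
        for name in ("symptom_prevalence", "ambiguity_rate", "colloquial_rate",
                     "colloquial_relevant_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise GenerationError(f"{name} must be in [0, 1], got {v}")
        if not 0.0 <= self.coder_noise <= 0.5:
            raise GenerationError("coder_noise must be in [0, 0.5]")
        if self.n_conversations < 1 or self.n_coders < 1:
            raise GenerationError("n_conversations and n_coders must be >= 1")
        lo, hi = self.turns_per_conversation
        if not (1 <= lo <= hi):
            raise GenerationError("turns_per_conversation must be a valid range")


@dataclass(frozen=True)
class TurnTruth:
    conversation_id: str
    turn_index: int
    positive: bool
    mechanism: str                 # {lexical, colloquial, decoy, filler}
    category: str | None
    proctcae_relevant: bool        # positive under the focused standard


@dataclass
class SyntheticCorpus:
    conversations: list[Conversation]
    truth: list[TurnTruth]
    scores: list[CoderScore]
    overrides: dict[TurnKey, bool]
    config: GeneratorConfig

    @property
    def truth_by_key(self) -> dict[TurnKey, TurnTruth]:
        return {(t.conversation_id, t.turn_index): t for t in self.truth}

    @property
    def n_turns(self) -> int:
        return sum(len(c.turns) for c in self.conversations)

    def broad_gold(self):
        return build_broad_gold(self.scores)


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = sorted(weights)
    p = np.array([weights[n] for n in names], dtype=float)
    return names[int(rng.choice(len(names), p=p / p.sum()))]


def generate(
    config: GeneratorConfig,
    seed_lexicon: KeywordLibrary,
    decoys: tuple[str, ...] = DEFAULT_DECOYS,
    paraphrases: tuple[tuple[str, str], ...] = DEFAULT_PARAPHRASES,
) -> SyntheticCorpus:
    """Generate a corpus with planted truth, coder scores and overrides.

    Deterministic under ``config.seed``.  Raises if the lexicon is empty, if
    a filler or paraphrase accidentally contains a lexicon term (this would
    break the planted truth), or if a slotted lexicon term fails to match its
    own rendering.
    """
    config.validate()
    if seed_lexicon.term_count == 0:
        raise GenerationError("seed lexicon must be nonempty")
    compiled = _CompiledLibrary(seed_lexicon)

    def hits(text: str) -> bool:
        turn = Turn(turn_index=0, speaker_role="patient", text=text)
        return detect_turn(normalize_and_tokenize(turn), compiled).detected

    for sentence in FILLER_SENTENCES:
        if hits(sentence):
            raise GenerationError(f"filler sentence contains a lexicon term: {sentence!r}")
    for surface, _cat in paraphrases:
        if hits(surface):
            raise GenerationError(f"paraphrase contains a lexicon term: {surface!r}")

    rng = np.random.default_rng(config.seed)
    entries = sorted(seed_lexicon.entries, key=lambda e: e.term)
    coder_ids = [f"coder{c + 1}" for c in range(config.n_coders)]

    # conversations are grouped under patients; dataset and stratum are
    # patient attributes (a speaker never crosses dataset samples)
    patient_of_conv: list[tuple[str, str, str]] = []  # (patient, dataset, stratum)
    i = 0
    pt = 0
    while i < config.n_conversations:
        n_here = int(rng.integers(1, 4))
        patient_id = f"pt{pt:04d}"
        dataset = _weighted_choice(rng, config.dataset_split)
        stratum = _weighted_choice(rng, config.strata)
        for _ in range(min(n_here, config.n_conversations - i)):
            patient_of_conv.append((patient_id, dataset, stratum))
            i += 1
        pt += 1

    conversations: list[Conversation] = []
    truth: list[TurnTruth] = []
    scores: list[CoderScore] = []
    lo, hi = config.turns_per_conversation

    for ci, (patient_id, dataset, stratum) in enumerate(patient_of_conv):
        cid = f"conv{ci:04d}"
        amb = (config.stratum_ambiguity or {}).get(stratum, config.ambiguity_rate)
        n_turns = int(rng.integers(lo, hi + 1))
        turns: list[Turn] = []
        for ti in range(n_turns):
            positive = bool(rng.random() < config.symptom_prevalence)
            if positive:
                if rng.random() < config.colloquial_rate:
                    surface, category = paraphrases[int(rng.integers(len(paraphrases)))]
                    text = surface.capitalize() + "."
                    relevant = bool(rng.random() < config.colloquial_relevant_fraction)
                    mechanism = "colloquial"
                    role = "patient" if rng.random() < 0.8 else "caregiver"
                else:
                    entry = entries[int(rng.integers(len(entries)))]
                    template = SYMPTOM_TEMPLATES[int(rng.integers(len(SYMPTOM_TEMPLATES)))]
                    text = template.format(term=entry.term)
                    category = sorted(entry.categories)[0]
                    relevant = True
                    mechanism = "lexical"
                    if not hits(text):
                        raise GenerationError(
                            f"lexicon term {entry.term!r} does not match its rendering {text!r}"
                        )
                    role = ("patient", "clinician", "caregiver")[
                        int(rng.choice(3, p=[0.6, 0.3, 0.1]))
                    ]
            else:
                category, relevant = None, False
                if rng.random() < amb:
                    decoy = decoys[int(rng.integers(len(decoys)))]
                    text = decoy.capitalize() + "."
                    mechanism = "decoy"
                    role = "clinician" if rng.random() < 0.6 else "patient"
                else:
                    text = FILLER_SENTENCES[int(rng.integers(len(FILLER_SENTENCES)))]
                    mechanism = "filler"
                    role = ("patient", "clinician", "caregiver")[
                        int(rng.choice(3, p=[0.4, 0.5, 0.1]))
                    ]
            turns.append(Turn(turn_index=ti, speaker_role=role, text=text))
            truth.append(
                TurnTruth(
                    conversation_id=cid,
                    turn_index=ti,
                    positive=positive,
                    mechanism=mechanism,
                    category=category,
                    proctcae_relevant=positive and relevant,
                )
            )
            base = 3 if positive else 0
            for coder in coder_ids:
                score = base
                if config.coder_noise > 0 and rng.random() < config.coder_noise:
                    score = min(3, max(0, score + (1 if rng.random() < 0.5 else -1)))
                scores.append(CoderScore(cid, ti, coder, score))
        conversations.append(
            Conversation(
                conversation_id=cid,
                patient_id=patient_id,
                dataset_label=dataset,
                metadata={config.stratum_key: stratum},
                turns=turns,
            )
        )

    # The focused-standard override sidecar corrects annotator error and
    # downgrades non-framework-relevant colloquial talk: after overrides the
    # focused labels equal the planted focused truth exactly.
    broad = {g.key: g.broad_positive for g in build_broad_gold(scores)}
    overrides = {
        (t.conversation_id, t.turn_index): t.proctcae_relevant
        for t in truth
        if broad[(t.conversation_id, t.turn_index)] != t.proctcae_relevant
    }
    return SyntheticCorpus(
        conversations=conversations,
        truth=truth,
        scores=scores,
        overrides=overrides,
        config=config,
    )


def decoy_hit_fraction(
    seed_lexicon: KeywordLibrary, decoys: tuple[str, ...] = DEFAULT_DECOYS
) -> float:
    """Fraction of decoy clauses that trigger a surviving lexicon match."""
    compiled = _CompiledLibrary(seed_lexicon)
    n_hit = 0
    for decoy in decoys:
        turn = Turn(turn_index=0, speaker_role="patient", text=decoy.capitalize() + ".")
        if detect_turn(normalize_and_tokenize(turn), compiled).detected:
            n_hit += 1
    return n_hit / len(decoys) if decoys else 0.0


def expected_performance(
    config: GeneratorConfig,
    seed_lexicon: KeywordLibrary | None = None,
    decoys: tuple[str, ...] = DEFAULT_DECOYS,
    standard: str = "broad",
) -> MetricSet:
    """Closed-form expected metrics of the matcher on a generated corpus (ε=0).

    Under the generative model, lexical positives always match and colloquial
    positives never do, so broad-standard sensitivity is ``1 − c``; false
    positives arise only from decoy clauses that overlap the lexicon, with
    per-negative-turn probability ``a·q`` where ``q`` is the decoy hit
    fraction.  Under the focused standard, the non-relevant share of
    colloquial turns is excluded, raising sensitivity to
    ``(1−c) / (1−c + c·r)`` with ``r`` the relevant fraction.
    """
    config.validate()
    p = config.symptom_prevalence
    c = config.colloquial_rate
    if config.stratum_ambiguity:
        weights = config.strata
        z = sum(weights.values())
        a = sum(
            w / z * config.stratum_ambiguity.get(name, config.ambiguity_rate)
            for name, w in weights.items()
        )
    else:
        a = config.ambiguity_rate
    q = decoy_hit_fraction(seed_lexicon, decoys) if seed_lexicon is not None else 0.0

    if standard == "broad":
        pos = p
        tp = p * (1.0 - c)
    elif standard == "proctcae":
        pos = p * (1.0 - c) + p * c * config.colloquial_relevant_fraction
        tp = p * (1.0 - c)
    else:
        raise GenerationError(f"unknown standard {standard!r}")
    neg = 1.0 - pos
    fp = (1.0 - p) * a * q           # decoy turns are negative under both standards
    fn = pos - tp
    tn = neg - fp
    sens = tp / pos if pos > 0 else None
    spec = tn / neg if neg > 0 else None
    prec = tp / (tp + fp) if (tp + fp) > 0 else None
    acc = tp + tn
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else None
    return MetricSet(sensitivity=sens, specificity=spec, precision=prec,
                     accuracy=acc, f1=f1)
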