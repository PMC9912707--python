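"""Support for the iterative library-development loop.

Library curation proceeds by (1) extracting the turns the gold standard
marks symptom-positive, (2) enumerating the words and short phrases spoken
in those turns with usage contexts (a KWIC view), and (3) recording human
include/exclude triage decisions in an append-only log that can be replayed
to produce the next library version.  The decision itself is human work;
this module only makes it reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple

from .annotation import GoldLabel
from .library import KeywordLibrary, make_entry
from .matching import KwicLine, kwic
from .transcripts import Conversation, Turn, normalize_and_tokenize

#: Function-word stoplist applied to single-word candidates only; phrases are
#: never stoplisted (a symptom phrase may legitimately contain "of" or "my").
DEFAULT_STOPLIST = frozenset(
    """a an and are as at be but by do did for from had has have he her him his i
    if in is it its me my no not of on or our she so that the their them they
    this to up was we were what when will with you your don't i'm it's that's
    you're""".split()
)


class MiningError(ValueError):
    pass


class PositiveTurn(NamedTuple):
    conversation_id: str
    turn: Turn


@dataclass
class Candidate:
    """A word or n-gram observed in symptom-positive turns, awaiting triage."""

    surface: str
    frequency: int
    contexts: list[KwicLine] = field(default_factory=list)
    status: str = "pending"                    # pending -> included | excluded
    categories: frozenset[str] = frozenset()


@dataclass(frozen=True)
class TriageDecision:
    surface: str
    status: str                                # {included, excluded}
    categories: frozenset[str] = frozenset()
    rationale: str = ""
    decider: str = ""


@dataclass
class TriageLog:
    """Append-only record of include/exclude decisions with rationale."""

    decisions: list[TriageDecision] = field(default_factory=list)

    def record(
        self,
        surface: str,
        status: str,
        categories=(),
        rationale: str = "",
        decider: str = "",
    ) -> None:
        if status not in ("included", "excluded"):
            raise MiningError(f"status must be included/excluded, got {status!r}")
        self.decisions.append(
            TriageDecision(
                surface=surface.strip().lower(),
                status=status,
                categories=frozenset([categories] if isinstance(categories, str) else categories),
                rationale=rationale,
                decider=decider,
            )
        )


def extract_positive_turns(
    corpus: list[Conversation], gold: list[GoldLabel], standard: str = "broad"
) -> list[PositiveTurn]:
    """Exactly the turns labelled positive under the chosen gold standard."""
    positive = {g.key for g in gold if g.positive(standard)}
    out = []
    for conv in corpus:
        for turn in conv.turns:
            if (conv.conversation_id, turn.turn_index) in positive:
                out.append(PositiveTurn(conv.conversation_id, turn))
    return out


def enumerate_candidates(
    positive_turns: list[PositiveTurn],
    existing: KeywordLibrary | None = None,
    ngram_max: int = 3,
    min_frequency: int = 1,
    stoplist: frozenset[str] = DEFAULT_STOPLIST,
    corpus: list[Conversation] | None = None,
    max_contexts: int = 3,
    context_window: int = 5,
) -> list[Candidate]:
    """Enumerate n-grams (n ≤ ``ngram_max``) spoken in symptom-positive turns.

    Candidates already in ``existing`` are omitted, as are stoplisted single
    words.  Frequency counts occurrences across the positive turns.  Sorted
    by descending frequency, then lexicographically.  When ``corpus`` is
    given, up to ``max_contexts`` KWIC lines per candidate are attached.
    """
    if ngram_max < 1:
        raise MiningError("ngram_max must be >= 1")
    known = existing.terms() if existing is not None else set()
    counts: dict[str, int] = {}
    for _cid, turn in positive_turns:
        texts = normalize_and_tokenize(turn).token_texts
        for n in range(1, ngram_max + 1):
            for i in range(len(texts) - n + 1):
                gram = " ".join(texts[i : i + n])
                counts[gram] = counts.get(gram, 0) + 1
    candidates = []
    for gram, freq in counts.items():
        if freq < min_frequency or gram in known:
            continue
        if " " not in gram and gram in stoplist:
            continue
        candidates.append(Candidate(surface=gram, frequency=freq))
    candidates.sort(key=lambda c: (-c.frequency, c.surface))
    if corpus is not None:
        for c in candidates:
            c.contexts = kwic(corpus, c.surface, window=context_window)[:max_contexts]
    return candidates


def apply_triage(
    candidates: list[Candidate],
    log: TriageLog,
    lib: KeywordLibrary,
    version_label: str | None = None,
) -> KeywordLibrary:
    """Produce the next library version from a triage log.

    Included candidates join the library with their decided categories and
    ``source="user"``; excluded ones are dropped.  Replaying the same log is
    idempotent.  An included candidate without a category, or a decision for
    an unknown candidate, is an error.
    """
    surfaces = {c.surface for c in candidates}
    final: dict[str, TriageDecision] = {}
    for d in log.decisions:
        if d.surface not in surfaces:
            raise MiningError(f"triage decision for unknown candidate {d.surface!r}")
        prev = final.get(d.surface)
        if prev is not None and prev.status != d.status:
            raise MiningError(
                f"conflicting triage decisions for {d.surface!r}; append a "
                "correcting decision with the same status instead"
            )
        final[d.surface] = d
    entries = list(lib.entries)
    have = lib.terms()
    for surface in sorted(final):
        d = final[surface]
        if d.status != "included":
            continue
        if not d.categories:
            raise MiningError(f"included candidate {surface!r} has no category")
        if surface in have:
            continue
        entries.append(make_entry(surface, d.categories, source="user"))
    return KeywordLibrary(
        entries=entries,
        exclusions=list(lib.exclusions),
        version_label=lib.version_label if version_label is None else version_label,
        category_vocabulary=lib.category_vocabulary,
    )


def candidate_statuses(candidates: list[Candidate], log: TriageLog) -> list[Candidate]:
    """Replay a triage log over candidates, returning updated copies."""
    final = {d.surface: d for d in log.decisions}
    out = []
    for c in candidates:
        d = final.get(c.surface)
        if d is None:
            out.append(c)
        else:
            out.append(replace(c, status=d.status, categories=d.categories))
    return out
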