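"""Turn-level keyword matching with contextual exclusions, and KWIC views.

Matching semantics
------------------
Detection runs at the level of the speaker turn.  A single-word term matches
any token equal to it after normalization (lowercasing, quote straightening);
a multi-word phrase matches a contiguous token sequence equal to its word
sequence.  Matching is at token boundaries, never substring — "red" must not
fire inside "bothered".  No regular-expression rules beyond the literal
library terms are applied.

Exclusion patterns are contextual suppressors: any candidate keyword match
whose character span lies fully inside an occurrence of an exclusion phrase
is moved to the suppressed list (e.g. an exclusion "deep breaths" silences a
"breaths" keyword during a physical exam instruction).  A turn is *detected*
iff at least one match survives exclusion.

Context never crosses turn boundaries: the approach deliberately ignores
responses to previous turns ("yes", "seven and three quarters"), which is a
known limitation of rule-based detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .library import KeywordLibrary
from .transcripts import Conversation, TokenizedTurn, normalize_and_tokenize, tokenize_phrase


@dataclass(frozen=True)
class Match:
    term: str
    span: tuple[int, int]           # char span in the turn text, half-open
    categories: frozenset[str]


@dataclass
class DetectionResult:
    conversation_id: str
    turn_index: int
    matches: list[Match] = field(default_factory=list)
    suppressed: list[tuple[Match, str]] = field(default_factory=list)

    @property
    def detected(self) -> bool:
        return len(self.matches) >= 1

    @property
    def matched_terms(self) -> list[str]:
        return sorted({m.term for m in self.matches})

    @property
    def categories(self) -> frozenset[str]:
        cats: frozenset[str] = frozenset()
        for m in self.matches:
            cats |= m.categories
        return cats


@dataclass(frozen=True)
class KwicLine:
    conversation_id: str
    turn_index: int
    left: str
    keyword: str
    right: str


class _CompiledLibrary:
    """Token-sequence index of a library, keyed by first word."""

    def __init__(self, lib: KeywordLibrary):
        self.terms: dict[str, list[tuple[tuple[str, ...], str, frozenset[str]]]] = {}
        for e in lib.entries:
            words = tokenize_phrase(e.term)
            if not words:
                continue
            self.terms.setdefault(words[0], []).append((words, e.term, e.categories))
        self.exclusions: dict[str, list[tuple[tuple[str, ...], str]]] = {}
        for x in lib.exclusions:
            words = tokenize_phrase(x.phrase)
            if not words:
                continue
            self.exclusions.setdefault(words[0], []).append((words, x.phrase))


def _occurrences(tokens, index) -> list[tuple[int, int, object]]:
    """All (start_char, end_char, payload) phrase occurrences in a token list."""
    texts = [t.text for t in tokens]
    out = []
    for i, tok in enumerate(tokens):
        for words, *payload in index.get(tok.text, ()):
            j = i + len(words)
            if j <= len(tokens) and tuple(texts[i:j]) == words:
                out.append((tok.start, tokens[j - 1].end, tuple(payload)))
    return out


def detect_turn(
    tokenized: TokenizedTurn,
    lib: KeywordLibrary | _CompiledLibrary,
    conversation_id: str = "",
) -> DetectionResult:
    """Detect symptom talk in one tokenized turn.

    Every occurrence of every library term is reported (overlaps included —
    detection is binary at turn level, so multiplicity is informational);
    occurrences fully contained inside an exclusion-phrase occurrence are
    reported under ``suppressed`` instead.
    """
    compiled = lib if isinstance(lib, _CompiledLibrary) else _CompiledLibrary(lib)
    tokens = tokenized.tokens
    candidates = _occurrences(tokens, compiled.terms)
    excl_spans = _occurrences(tokens, compiled.exclusions)
    result = DetectionResult(
        conversation_id=conversation_id, turn_index=tokenized.turn.turn_index
    )
    for start, end, (term, cats) in sorted(candidates, key=lambda c: (c[0], c[1], c[2][0])):
        match = Match(term=term, span=(start, end), categories=cats)
        blocker = next(
            (phrase for (xs, xe, (phrase,)) in excl_spans if xs <= start and end <= xe),
            None,
        )
        if blocker is None:
            result.matches.append(match)
        else:
            result.suppressed.append((match, blocker))
    return result


def detect_corpus(
    corpus: list[Conversation], lib: KeywordLibrary
) -> list[DetectionResult]:
    """Run detection over every turn of every conversation (one result per turn)."""
    compiled = _CompiledLibrary(lib)
    results = []
    for conv in corpus:
        for turn in conv.turns:
            results.append(
                detect_turn(normalize_and_tokenize(turn), compiled, conv.conversation_id)
            )
    return results


def kwic(
    corpus: list[Conversation], term: str, window: int = 7
) -> list[KwicLine]:
    """Keyword-in-context concordance for ``term`` over a corpus.

    One line per occurrence, with up to ``window`` tokens of context on each
    side, truncated at turn boundaries (context never crosses turns).
    Exclusions are not applied: KWIC is a curation view, and seeing excluded
    contexts is the point.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    words = tokenize_phrase(term)
    lines: list[KwicLine] = []
    if not words:
        return lines
    for conv in corpus:
        for turn in conv.turns:
            tk = normalize_and_tokenize(turn)
            texts = list(tk.token_texts)
            for i in range(len(texts) - len(words) + 1):
                if tuple(texts[i : i + len(words)]) == words:
                    lines.append(
                        KwicLine(
                            conversation_id=conv.conversation_id,
                            turn_index=turn.turn_index,
                            left=" ".join(texts[max(0, i - window) : i]),
                            keyword=" ".join(words),
                            right=" ".join(texts[i + len(words) : i + len(words) + window]),
                        )
                    )
    return lines
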