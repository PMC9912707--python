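"""Keyword library model and I/O.

A keyword library is a curated, versioned set of literal words and phrases
used to detect turn-level symptom talk in transcribed clinical conversations.
Each entry carries one or more (nonexclusive) PRO-CTCAE symptom-category
assignments and provenance flags; a library may additionally carry exclusion
patterns — phrases whose occurrence suppresses any keyword match contained
within them (the canonical example being exam-context "deep breaths").

Terms are literal strings, never regexes: matching semantics live entirely in
:mod:`symtalk.matching`, which keeps the library auditable by non-programmers.
Morphological variants (plural, -ing forms) are separate explicit entries
rather than stems for the same reason.
"""

from __future__ import annotations

import csv
import io
import logging
import os
from dataclasses import dataclass, field, replace

import yaml

logger = logging.getLogger(__name__)

#: Default category vocabulary: PRO-CTCAE symptom system groupings.  The
#: PRO-CTCAE framework covers ~80 clinically relevant cancer symptoms; for
#: library curation they are grouped into body-system classes.  "med" marks
#: entries that are medications used to treat symptoms in a class and is kept
#: in the vocabulary so medication terms can be categorised by the symptom
#: they treat.
DEFAULT_CATEGORIES: tuple[str, ...] = (
    "pain",
    "GI",
    "sleep/wake",
    "neurological",
    "cutaneous",
    "mood/anxiety",
    "respiratory",
    "oral",
    "sexual",
    "other",
)

VALID_SOURCES = ("development-corpus", "a-priori", "validation-adjustment", "user")


class LibraryError(ValueError):
    """Raised for schema or invariant violations in a keyword library."""


@dataclass(frozen=True)
class KeywordEntry:
    """A single literal term (single word or multi-word phrase).

    Parameters
    ----------
    term
        Lowercase surface form, no leading/trailing whitespace.
    categories
        Nonexclusive set of symptom-category identifiers (at least one).
    is_medication
        Term is a medication commonly used to treat a relevant symptom.
    is_clinician_authored
        Term originates from clinician rather than patient speech; users
        building patient-voice-only libraries may filter these out.
    is_symptom_specific
        Term names a specific symptom (as opposed to generic management or
        assessment language).
    source
        Provenance tag: ``development-corpus`` (mined from transcripts),
        ``a-priori`` (brainstormed or imported from prior work),
        ``validation-adjustment`` (added after a validation round), ``user``.
    """

    term: str
    categories: frozenset[str]
    is_medication: bool = False
    is_clinician_authored: bool = False
    is_symptom_specific: bool = True
    source: str = "user"

    def __post_init__(self) -> None:
        if not self.term or self.term != self.term.strip():
            raise LibraryError(f"invalid term {self.term!r}: empty or untrimmed")
        if self.term != self.term.lower():
            raise LibraryError(f"term {self.term!r} must be lowercase")
        if not self.categories:
            raise LibraryError(f"term {self.term!r} has no categories")
        if self.source not in VALID_SOURCES:
            raise LibraryError(
                f"term {self.term!r}: unknown source {self.source!r} "
                f"(allowed: {', '.join(VALID_SOURCES)})"
            )
        object.__setattr__(self, "categories", frozenset(self.categories))


@dataclass(frozen=True)
class ExclusionPattern:
    """A phrase whose occurrence suppresses keyword matches inside its span.

    Exclusions are contextual suppression patterns, not term deletions: an
    exclusion only silences candidate matches fully contained within one of
    its occurrences, so "deep breaths" (physical-exam context) suppresses a
    "breaths" keyword inside that phrase while leaving other occurrences of
    "breaths" detectable.
    """

    phrase: str
    rationale: str = ""

    def __post_init__(self) -> None:
        if not self.phrase or self.phrase != self.phrase.strip():
            raise LibraryError(f"invalid exclusion {self.phrase!r}")
        if self.phrase != self.phrase.lower():
            raise LibraryError(f"exclusion {self.phrase!r} must be lowercase")


@dataclass
class KeywordLibrary:
    """A versioned keyword library: entries, exclusions, category vocabulary."""

    entries: list[KeywordEntry] = field(default_factory=list)
    exclusions: list[ExclusionPattern] = field(default_factory=list)
    version_label: str = "unversioned"
    category_vocabulary: frozenset[str] = frozenset(DEFAULT_CATEGORIES)

    def __post_init__(self) -> None:
        self.category_vocabulary = frozenset(self.category_vocabulary)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.term in seen:
                raise LibraryError(f"duplicate term {e.term!r}")
            seen.add(e.term)
            unknown = e.categories - self.category_vocabulary
            if unknown:
                raise LibraryError(
                    f"term {e.term!r}: unknown categories {sorted(unknown)}; "
                    f"allowed: {sorted(self.category_vocabulary)}"
                )
        phrases = [x.phrase for x in self.exclusions]
        if len(phrases) != len(set(phrases)):
            raise LibraryError("duplicate exclusion phrases")

    @property
    def term_count(self) -> int:
        return len(self.entries)

    def terms(self) -> set[str]:
        return {e.term for e in self.entries}

    def get(self, term: str) -> KeywordEntry:
        for e in self.entries:
            if e.term == term:
                return e
        raise KeyError(term)

    def __contains__(self, term: str) -> bool:
        return any(e.term == term for e in self.entries)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KeywordLibrary):
            return NotImplemented
        return (
            sorted(self.entries, key=lambda e: e.term)
            == sorted(other.entries, key=lambda e: e.term)
            and sorted(self.exclusions, key=lambda x: x.phrase)
            == sorted(other.exclusions, key=lambda x: x.phrase)
            and self.version_label == other.version_label
            and self.category_vocabulary == other.category_vocabulary
        )


@dataclass
class LibraryDiff:
    """Difference between two library versions.

    ``apply_diff(a, diff_libraries(a, b)) == b`` holds entry-for-entry; in
    particular ``|B| = |A| + |added| - |removed|``.
    """

    added: list[KeywordEntry] = field(default_factory=list)
    removed: list[KeywordEntry] = field(default_factory=list)
    exclusions_added: list[ExclusionPattern] = field(default_factory=list)
    exclusions_removed: list[ExclusionPattern] = field(default_factory=list)
    recategorized: list[tuple[str, frozenset[str], frozenset[str]]] = field(
        default_factory=list
    )

    @property
    def is_empty(self) -> bool:
        return not (
            self.added
            or self.removed
            or self.exclusions_added
            or self.exclusions_removed
            or self.recategorized
        )


# ---------------------------------------------------------------------------
# construction helpers

def make_entry(
    term: str,
    categories,
    *,
    is_medication: bool = False,
    is_clinician_authored: bool = False,
    is_symptom_specific: bool = True,
    source: str = "user",
) -> KeywordEntry:
    """Convenience constructor accepting any iterable of categories."""
    if isinstance(categories, str):
        categories = [categories]
    return KeywordEntry(
        term=term.strip().lower(),
        categories=frozenset(categories),
        is_medication=is_medication,
        is_clinician_authored=is_clinician_authored,
        is_symptom_specific=is_symptom_specific,
        source=source,
    )


def _collapse_duplicates(entries: list[KeywordEntry]) -> list[KeywordEntry]:
    """Collapse case-insensitive duplicate terms, unioning categories.

    Categories are nonexclusive, so two rows for one term are interpreted as
    one entry in several categories; flags are OR-ed and the first source wins.
    """
    by_term: dict[str, KeywordEntry] = {}
    for e in entries:
        key = e.term
        if key in by_term:
            prev = by_term[key]
            logger.warning("duplicate term %r collapsed; categories unioned", key)
            by_term[key] = replace(
                prev,
                categories=prev.categories | e.categories,
                is_medication=prev.is_medication or e.is_medication,
                is_clinician_authored=prev.is_clinician_authored
                or e.is_clinician_authored,
                is_symptom_specific=prev.is_symptom_specific or e.is_symptom_specific,
            )
        else:
            by_term[key] = e
    return list(by_term.values())


# ---------------------------------------------------------------------------
# I/O

_BOOLS = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False, "": False}

TABULAR_COLUMNS = [
    "term",
    "type",
    "categories",
    "is_medication",
    "is_clinician_authored",
    "is_symptom_specific",
    "source",
    "rationale",
]


def _parse_bool(value: str, line: int, column: str) -> bool:
    try:
        return _BOOLS[str(value).strip().lower()]
    except KeyError:
        raise LibraryError(f"line {line}: column {column!r}: not a boolean: {value!r}")


def load_library(path: str | os.PathLike, format: str | None = None) -> KeywordLibrary:
    """Load a keyword library from ``path``.

    ``format`` is ``"tabular"`` (delimiter-separated, header row) or
    ``"structured-text"`` (YAML document); when omitted it is inferred from
    the file extension (.csv/.tsv vs .yaml/.yml).  Duplicate terms collapse to
    one entry with the union of categories (logged as a warning).  Malformed
    rows raise :class:`LibraryError` naming the line; unknown categories raise
    listing the allowed vocabulary.  An empty library is an error.
    """
    path = os.fspath(path)
    fmt = format or _infer_format(path)
    with open(path, "r", encoding="utf-8") as fh:
        text = fh.read()
    if fmt == "tabular":
        lib = _load_tabular(text, path)
    elif fmt == "structured-text":
        lib = _load_structured(text, path)
    else:
        raise LibraryError(f"unknown library format {fmt!r}")
    if lib.term_count == 0:
        raise LibraryError(f"{path}: a library must contain at least 1 entry")
    logger.info("loaded library %r: %d terms, %d exclusions",
                lib.version_label, lib.term_count, len(lib.exclusions))
    return lib


def _infer_format(path: str) -> str:
    ext = os.path.splitext(path)[1].lower()
    if ext in (".yaml", ".yml"):
        return "structured-text"
    return "tabular"


def _load_tabular(text: str, origin: str) -> KeywordLibrary:
    version_label = "unversioned"
    lines = text.splitlines()
    body_start = 0
    for ln in lines:
        if ln.startswith("#"):
            body_start += 1
            if ln.lower().startswith("# version:"):
                version_label = ln.split(":", 1)[1].strip()
        else:
            break
    body = "\n".join(lines[body_start:])
    if not body.strip():
        raise LibraryError(f"{origin}: empty library file")
    first = body.splitlines()[0]
    delimiter = "\t" if "\t" in first else ","
    reader = csv.DictReader(io.StringIO(body), delimiter=delimiter)
    if reader.fieldnames is None or "term" not in reader.fieldnames:
        raise LibraryError(f"{origin}: missing header row with a 'term' column")
    entries: list[KeywordEntry] = []
    exclusions: list[ExclusionPattern] = []
    for i, row in enumerate(reader, start=body_start + 2):
        term = (row.get("term") or "").strip().lower()
        if not term:
            raise LibraryError(f"{origin}: line {i}: empty term")
        kind = (row.get("type") or "keyword").strip().lower()
        if kind == "exclusion":
            exclusions.append(
                ExclusionPattern(phrase=term, rationale=(row.get("rationale") or "").strip())
            )
            continue
        if kind != "keyword":
            raise LibraryError(f"{origin}: line {i}: unknown row type {kind!r}")
        cats = [c.strip() for c in (row.get("categories") or "").split(";") if c.strip()]
        if not cats:
            raise LibraryError(f"{origin}: line {i}: term {term!r} has no categories")
        try:
            entries.append(
                KeywordEntry(
                    term=term,
                    categories=frozenset(cats),
                    is_medication=_parse_bool(row.get("is_medication", ""), i, "is_medication"),
                    is_clinician_authored=_parse_bool(
                        row.get("is_clinician_authored", ""), i, "is_clinician_authored"
                    ),
                    is_symptom_specific=_parse_bool(
                        row.get("is_symptom_specific", "true"), i, "is_symptom_specific"
                    ),
                    source=(row.get("source") or "user").strip() or "user",
                )
            )
        except LibraryError as err:
            raise LibraryError(f"{origin}: line {i}: {err}") from None
    return KeywordLibrary(
        entries=_collapse_duplicates(entries),
        exclusions=exclusions,
        version_label=version_label,
    )


def _load_structured(text: str, origin: str) -> KeywordLibrary:
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as err:
        raise LibraryError(f"{origin}: not valid structured text: {err}") from None
    if not isinstance(doc, dict):
        raise LibraryError(f"{origin}: empty library file")
    entries = []
    for i, item in enumerate(doc.get("entries") or [], start=1):
        if not isinstance(item, dict) or "term" not in item:
            raise LibraryError(f"{origin}: entry {i}: malformed (need a 'term' key)")
        entries.append(
            make_entry(
                item["term"],
                item.get("categories") or [],
                is_medication=bool(item.get("is_medication", False)),
                is_clinician_authored=bool(item.get("is_clinician_authored", False)),
                is_symptom_specific=bool(item.get("is_symptom_specific", True)),
                source=item.get("source", "user"),
            )
        )
    exclusions = [
        ExclusionPattern(phrase=str(x["phrase"]).strip().lower(),
                         rationale=str(x.get("rationale", "")))
        for x in (doc.get("exclusions") or [])
    ]
    vocab = doc.get("category_vocabulary")
    kwargs = {"category_vocabulary": frozenset(vocab)} if vocab else {}
    return KeywordLibrary(
        entries=_collapse_duplicates(entries),
        exclusions=exclusions,
        version_label=str(doc.get("version_label", "unversioned")),
        **kwargs,
    )


def save_library(lib: KeywordLibrary, path: str | os.PathLike, format: str | None = None) -> None:
    """Write ``lib`` to ``path``; ``load_library(save_library(lib))`` is the identity."""
    path = os.fspath(path)
    fmt = format or _infer_format(path)
    if fmt == "tabular":
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write(f"# version: {lib.version_label}\n")
            writer = csv.DictWriter(fh, fieldnames=TABULAR_COLUMNS)
            writer.writeheader()
            for e in sorted(lib.entries, key=lambda e: e.term):
                writer.writerow(
                    {
                        "term": e.term,
                        "type": "keyword",
                        "categories": ";".join(sorted(e.categories)),
                        "is_medication": str(e.is_medication).lower(),
                        "is_clinician_authored": str(e.is_clinician_authored).lower(),
                        "is_symptom_specific": str(e.is_symptom_specific).lower(),
                        "source": e.source,
                        "rationale": "",
                    }
                )
            for x in sorted(lib.exclusions, key=lambda x: x.phrase):
                writer.writerow({"term": x.phrase, "type": "exclusion", "rationale": x.rationale})
    elif fmt == "structured-text":
        doc = {
            "version_label": lib.version_label,
            "category_vocabulary": sorted(lib.category_vocabulary),
            "entries": [
                {
                    "term": e.term,
                    "categories": sorted(e.categories),
                    "is_medication": e.is_medication,
                    "is_clinician_authored": e.is_clinician_authored,
                    "is_symptom_specific": e.is_symptom_specific,
                    "source": e.source,
                }
                for e in sorted(lib.entries, key=lambda e: e.term)
            ],
            "exclusions": [
                {"phrase": x.phrase, "rationale": x.rationale}
                for x in sorted(lib.exclusions, key=lambda x: x.phrase)
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False, allow_unicode=True)
    else:
        raise LibraryError(f"unknown library format {fmt!r}")


# ---------------------------------------------------------------------------
# diff / filter

def diff_libraries(a: KeywordLibrary, b: KeywordLibrary) -> LibraryDiff:
    """Compute the entry/exclusion difference turning library ``a`` into ``b``."""
    a_terms = {e.term: e for e in a.entries}
    b_terms = {e.term: e for e in b.entries}
    added = [b_terms[t] for t in sorted(b_terms.keys() - a_terms.keys())]
    removed = [a_terms[t] for t in sorted(a_terms.keys() - b_terms.keys())]
    recategorized = []
    for t in sorted(a_terms.keys() & b_terms.keys()):
        if a_terms[t] != b_terms[t]:
            # flag changes are folded into remove+add to keep apply exact
            if a_terms[t].categories != b_terms[t].categories and (
                replace(a_terms[t], categories=b_terms[t].categories) == b_terms[t]
            ):
                recategorized.append((t, a_terms[t].categories, b_terms[t].categories))
            else:
                removed.append(a_terms[t])
                added.append(b_terms[t])
    a_excl = {x.phrase: x for x in a.exclusions}
    b_excl = {x.phrase: x for x in b.exclusions}
    return LibraryDiff(
        added=added,
        removed=removed,
        exclusions_added=[b_excl[p] for p in sorted(b_excl.keys() - a_excl.keys())],
        exclusions_removed=[a_excl[p] for p in sorted(a_excl.keys() - b_excl.keys())],
        recategorized=recategorized,
    )


def apply_diff(a: KeywordLibrary, diff: LibraryDiff, version_label: str | None = None) -> KeywordLibrary:
    """Apply ``diff`` to ``a``: ``apply_diff(a, diff_libraries(a, b))`` equals ``b``."""
    removed_terms = {e.term for e in diff.removed}
    entries = {e.term: e for e in a.entries if e.term not in removed_terms}
    for e in diff.added:
        entries[e.term] = e
    for term, _old, new in diff.recategorized:
        if term not in entries:
            raise LibraryError(f"recategorized term {term!r} not in library")
        entries[term] = replace(entries[term], categories=new)
    removed_phrases = {x.phrase for x in diff.exclusions_removed}
    exclusions = [x for x in a.exclusions if x.phrase not in removed_phrases]
    exclusions.extend(diff.exclusions_added)
    return KeywordLibrary(
        entries=sorted(entries.values(), key=lambda e: e.term),
        exclusions=sorted(exclusions, key=lambda x: x.phrase),
        version_label=a.version_label if version_label is None else version_label,
        category_vocabulary=a.category_vocabulary,
    )


def filter_library(
    lib: KeywordLibrary,
    *,
    drop_medication: bool = False,
    drop_clinician_authored: bool = False,
    drop_symptom_specific: bool = False,
) -> KeywordLibrary:
    """Drop entries carrying any of the selected provenance flags.

    Supports downstream users who want, e.g., a patient-voice library without
    clinician-authored language or without medication names.  Exclusions are
    unchanged.  An empty result is an error.
    """
    kept = [
        e
        for e in lib.entries
        if not (
            (drop_medication and e.is_medication)
            or (drop_clinician_authored and e.is_clinician_authored)
            or (drop_symptom_specific and e.is_symptom_specific)
        )
    ]
    if not kept:
        raise LibraryError("filter removed every entry; a library must be nonempty")
    return KeywordLibrary(
        entries=kept,
        exclusions=list(lib.exclusions),
        version_label=lib.version_label,
        category_vocabulary=lib.category_vocabulary,
    )
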