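"""symtalk: rule-based detection of symptom talk in clinical conversations.

A curated keyword library grounded in the PRO-CTCAE symptom framework is
applied at the speaker-turn level of transcribed oncology conversations,
with contextual exclusion patterns, gold-standard construction from ordinal
coder scores, confusion-matrix evaluation, KWIC concordance and term-mining
support for iterative library curation, and a synthetic-conversation
generator with planted ground truth.
"""

from importlib import resources

from .annotation import (
    CoderScore,
    GoldLabel,
    ReliabilityReport,
    apply_proctcae_overrides,
    build_broad_gold,
    cohen_kappa,
    fleiss_kappa,
    interrater_kappa,
)
from .evaluation import (
    ConfusionCounts,
    EvaluationReport,
    MetricSet,
    ReviewSample,
    confusion,
    evaluate,
    metrics,
    sample_for_review,
    stratified_report,
)
from .library import (
    ExclusionPattern,
    KeywordEntry,
    KeywordLibrary,
    LibraryDiff,
    apply_diff,
    diff_libraries,
    filter_library,
    load_library,
    make_entry,
    save_library,
)
from .matching import DetectionResult, KwicLine, Match, detect_corpus, detect_turn, kwic
from .mining import (
    Candidate,
    TriageLog,
    apply_triage,
    enumerate_candidates,
    extract_positive_turns,
)
from .synthetic import (
    GeneratorConfig,
    SyntheticCorpus,
    expected_performance,
    generate,
)
from .transcripts import (
    Conversation,
    TokenizedTurn,
    Turn,
    normalize_and_tokenize,
    read_corpus,
    write_corpus,
)

__version__ = "0.1.0"


def seed_lexicon() -> KeywordLibrary:
    """The shipped starter library: a small, format-compatible lexicon of
    colloquial and clinical symptom terms with PRO-CTCAE category groupings
    and the exam-context "deep breath(s)" exclusions.  Intended as a working
    default and a template; users with a full curated library load their own
    file instead."""
    with resources.as_file(
        resources.files("symtalk").joinpath("data/seed_lexicon.csv")
    ) as path:
        return load_library(path, format="tabular")


__all__ = [name for name in dir() if not name.startswith("_")]
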