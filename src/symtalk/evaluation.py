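"""Confusion-matrix evaluation of turn-level detection against a gold standard.

Five metrics are computed from turn-level confusion counts:

* sensitivity (recall) = TP / (TP + FN)
* specificity          = TN / (TN + FP)
* precision            = TP / (TP + FP)
* accuracy             = (TP + TN) / (TP + TN + FP + FN)
* F1                   = 2·TP / (2·TP + FP + FN)

A metric whose denominator is zero is *undefined* and surfaces as ``None``
(never silently 0 — small strata would otherwise be biased).  Display
rounding is half-up to 2 decimals; raw values are retained.

Stratified reports partition turns by a conversation-metadata key (e.g.
patient self-reported race); race is a patient attribute, so stratum
assignment is at the conversation level.  The module also provides the
seeded sampling frame used to draw misclassified (FP, FN) and
properly-classified (TP) turns for qualitative review.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

from .annotation import GoldLabel, TurnKey
from .matching import DetectionResult
from .transcripts import Conversation

METRIC_NAMES = ("sensitivity", "specificity", "precision", "accuracy", "f1")


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.tn + other.tn, self.fn + other.fn
        )


@dataclass(frozen=True)
class MetricSet:
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    accuracy: float | None
    f1: float | None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        """Half-up rounding for table display; raw values stay on the object."""
        q = Decimal(10) ** -ndigits
        return {
            name: (
                None
                if value is None
                else float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
            )
            for name, value in self.as_dict().items()
        }

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass
class EvaluationReport:
    gold_standard_label: str                   # {broad, proctcae}
    counts: ConfusionCounts
    metrics: MetricSet
    strata: dict[str, tuple[ConfusionCounts, MetricSet]] | None = None


@dataclass
class ReviewSample:
    turns: list[tuple[TurnKey, str]]           # (turn key, class in {TP, FP, FN})
    seed: int
    per_class_sizes: dict[str, int] = field(default_factory=dict)
    per_dataset_sizes: dict[str, int] = field(default_factory=dict)
    n_unique_patients: int = 0


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def metrics(c: ConfusionCounts) -> MetricSet:
    """The five turn-level metrics from confusion counts (total must be > 0)."""
    if c.total == 0:
        raise EvaluationError("cannot compute metrics on zero evaluated turns")
    return MetricSet(
        sensitivity=_ratio(c.tp, c.tp + c.fn),
        specificity=_ratio(c.tn, c.tn + c.fp),
        precision=_ratio(c.tp, c.tp + c.fp),
        accuracy=_ratio(c.tp + c.tn, c.total),
        f1=_ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
    )


def _paired(
    detections: list[DetectionResult], gold: list[GoldLabel]
) -> list[tuple[TurnKey, bool, bool, GoldLabel]]:
    det_by_key = {(d.conversation_id, d.turn_index): d for d in detections}
    gold_by_key = {g.key: g for g in gold}
    missing_gold = sorted(det_by_key.keys() - gold_by_key.keys())
    missing_det = sorted(gold_by_key.keys() - det_by_key.keys())
    if missing_gold or missing_det:
        raise EvaluationError(
            "detections and gold standard cover different turns; "
            f"missing gold for {missing_gold[:5]}, missing detections for {missing_det[:5]}"
        )
    return [
        (key, det_by_key[key].detected, gold_by_key[key], gold_by_key[key])
        for key in sorted(det_by_key)
    ]


def classify_turns(
    detections: list[DetectionResult], gold: list[GoldLabel], standard: str = "broad"
) -> dict[TurnKey, str]:
    """Map every evaluated turn to its confusion class {TP, FP, TN, FN}."""
    out = {}
    for key, detected, g, _ in _paired(detections, gold):
        positive = g.positive(standard)
        if detected and positive:
            out[key] = "TP"
        elif detected and not positive:
            out[key] = "FP"
        elif not detected and positive:
            out[key] = "FN"
        else:
            out[key] = "TN"
    return out


def confusion(
    detections: list[DetectionResult], gold: list[GoldLabel], standard: str = "broad"
) -> ConfusionCounts:
    classes = classify_turns(detections, gold, standard)
    return ConfusionCounts(
        tp=sum(1 for v in classes.values() if v == "TP"),
        fp=sum(1 for v in classes.values() if v == "FP"),
        tn=sum(1 for v in classes.values() if v == "TN"),
        fn=sum(1 for v in classes.values() if v == "FN"),
    )


def evaluate(
    detections: list[DetectionResult], gold: list[GoldLabel], standard: str = "broad"
) -> EvaluationReport:
    c = confusion(detections, gold, standard)
    return EvaluationReport(gold_standard_label=standard, counts=c, metrics=metrics(c))


def stratified_report(
    detections: list[DetectionResult],
    gold: list[GoldLabel],
    conversations: list[Conversation],
    standard: str = "broad",
    stratify_by: str = "race",
) -> EvaluationReport:
    """Overall report plus per-stratum counts/metrics by a metadata key.

    Conversations lacking the key fall into a ``"Missing"`` stratum; strata
    therefore partition the evaluated turns and their counts sum to the
    overall counts.
    """
    stratum_of = {
        c.conversation_id: c.metadata.get(stratify_by, "Missing") or "Missing"
        for c in conversations
    }
    classes = classify_turns(detections, gold, standard)
    per: dict[str, dict[str, int]] = {}
    for (cid, _ti), cls in classes.items():
        stratum = stratum_of.get(cid, "Missing")
        per.setdefault(stratum, {"TP": 0, "FP": 0, "TN": 0, "FN": 0})[cls] += 1
    strata = {}
    for name in sorted(per):
        c = ConfusionCounts(per[name]["TP"], per[name]["FP"], per[name]["TN"], per[name]["FN"])
        strata[name] = (c, metrics(c))
    overall = confusion(detections, gold, standard)
    return EvaluationReport(
        gold_standard_label=standard,
        counts=overall,
        metrics=metrics(overall),
        strata=strata,
    )


def sample_for_review(
    detections: list[DetectionResult],
    gold: list[GoldLabel],
    conversations: list[Conversation],
    n_fp_fn: int,
    n_tp: int,
    seed: int,
    standard: str = "broad",
    balance_by: str = "dataset_label",
    max_per_patient: int | None = None,
) -> ReviewSample:
    """Seeded sampling frame for qualitative review of FP/FN and TP turns.

    Draws ``n_fp_fn`` misclassified (FP ∪ FN) and ``n_tp`` properly
    classified turns, keeping per-dataset proportions as even as the pools
    allow (round-robin over datasets) and enforcing an optional per-patient
    cap so that no single patient dominates the sample.  Reproducible under a
    fixed seed; infeasible requests raise naming the binding constraint.
    """
    if n_fp_fn < 0 or n_tp < 0:
        raise EvaluationError("requested sample sizes must be non-negative")
    conv_info = {c.conversation_id: c for c in conversations}
    classes = classify_turns(detections, gold, standard)
    rng = np.random.default_rng(seed)

    def dataset_of(key: TurnKey) -> str:
        conv = conv_info.get(key[0])
        return getattr(conv, balance_by, "user") if conv is not None else "user"

    def patient_of(key: TurnKey) -> str:
        conv = conv_info.get(key[0])
        return conv.patient_id if conv is not None else key[0]

    patient_counts: dict[str, int] = {}
    chosen: list[tuple[TurnKey, str]] = []

    def draw(pool_classes: tuple[str, ...], n_wanted: int) -> None:
        pool = sorted(k for k, cls in classes.items() if cls in pool_classes)
        if len(pool) < n_wanted:
            raise EvaluationError(
                f"requested {n_wanted} turns from classes {pool_classes} "
                f"but only {len(pool)} are available"
            )
        by_ds: dict[str, list[TurnKey]] = {}
        for k in pool:
            by_ds.setdefault(dataset_of(k), []).append(k)
        for keys in by_ds.values():
            rng.shuffle(keys)  # type: ignore[arg-type]
        taken = 0
        order = sorted(by_ds)
        exhausted: set[str] = set()
        while taken < n_wanted:
            progressed = False
            for ds in order:
                if taken >= n_wanted:
                    break
                if ds in exhausted:
                    continue
                keys = by_ds[ds]
                while keys:
                    k = keys.pop()
                    pid = patient_of(k)
                    if max_per_patient is not None and patient_counts.get(pid, 0) >= max_per_patient:
                        continue
                    chosen.append((k, classes[k]))
                    patient_counts[pid] = patient_counts.get(pid, 0) + 1
                    taken += 1
                    progressed = True
                    break
                else:
                    exhausted.add(ds)
            if not progressed:
                raise EvaluationError(
                    f"cannot draw {n_wanted} turns from classes {pool_classes}: "
                    f"per-patient cap of {max_per_patient} is binding after {taken} draws"
                )

    draw(("FP", "FN"), n_fp_fn)
    draw(("TP",), n_tp)

    per_class: dict[str, int] = {}
    per_dataset: dict[str, int] = {}
    for key, cls in chosen:
        per_class[cls] = per_class.get(cls, 0) + 1
        ds = dataset_of(key)
        per_dataset[ds] = per_dataset.get(ds, 0) + 1
    return ReviewSample(
        turns=chosen,
        seed=seed,
        per_class_sizes=per_class,
        per_dataset_sizes=per_dataset,
        n_unique_patients=len({patient_of(k) for k, _ in chosen}),
    )
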