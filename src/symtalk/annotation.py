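"""Gold-standard construction from coder scores, and inter-rater reliability.

Coders score each speaker turn for symptom relevance on a 0–3 ordinal scale
(3 = certainly symptom talk).  Two binary gold standards are derived:

* **broad**: a turn is positive iff the mean of available coder scores is
  at least 2.0 (closed bound — a mean of exactly 2.0 is positive).
* **PRO-CTCAE-focused**: the broad labels, manually overridden per turn to
  correct annotator errors and to restrict positivity to symptom content the
  PRO-CTCAE framework actually targets.  Overrides are an explicit sidecar
  (turn key → boolean) so the focused standard stays reproducible and
  auditable.

Reliability is chance-corrected agreement on binarized labels: Cohen's kappa
κ = (p_o − p_e)/(1 − p_e) averaged over coder pairs, or Fleiss' kappa for a
fully crossed multi-rater design.  Both are implemented from the closed
forms; when chance agreement p_e = 1 (all raters constant and identical)
kappa is undefined and reported as NaN with a warning.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from itertools import combinations

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TurnKey = tuple[str, int]  # (conversation_id, turn_index)

BROAD_THRESHOLD = 2.0


class AnnotationError(ValueError):
    pass


@dataclass(frozen=True)
class CoderScore:
    conversation_id: str
    turn_index: int
    coder_id: str
    score: int

    def __post_init__(self) -> None:
        if self.score not in (0, 1, 2, 3):
            raise AnnotationError(
                f"score must be an integer in 0..3, got {self.score!r} "
                f"({self.conversation_id}/{self.turn_index}/{self.coder_id})"
            )

    @property
    def key(self) -> TurnKey:
        return (self.conversation_id, self.turn_index)


@dataclass(frozen=True)
class GoldLabel:
    conversation_id: str
    turn_index: int
    mean_score: float
    broad_positive: bool
    proctcae_positive: bool
    override_source: str = "none"   # {none, manual}

    @property
    def key(self) -> TurnKey:
        return (self.conversation_id, self.turn_index)

    def positive(self, standard: str) -> bool:
        if standard == "broad":
            return self.broad_positive
        if standard == "proctcae":
            return self.proctcae_positive
        raise AnnotationError(f"unknown gold standard {standard!r}")


@dataclass(frozen=True)
class ReliabilityReport:
    n_conversations: int
    n_turns: int
    n_coders: int
    kappa_statistic: float
    kappa_kind: str   # {cohen-pairwise-mean, fleiss}


def build_broad_gold(scores: list[CoderScore]) -> list[GoldLabel]:
    """Mean coder score per turn, thresholded at ≥ 2.0.

    Every scored turn yields exactly one label; a duplicate (turn, coder)
    pair is an error.  Turns scored by a single coder are allowed.
    """
    if not scores:
        raise AnnotationError("no coder scores supplied")
    seen: set[tuple[TurnKey, str]] = set()
    per_turn: dict[TurnKey, list[int]] = {}
    for s in scores:
        pair = (s.key, s.coder_id)
        if pair in seen:
            raise AnnotationError(f"duplicate score for turn {s.key} coder {s.coder_id}")
        seen.add(pair)
        per_turn.setdefault(s.key, []).append(s.score)
    labels = []
    for key in sorted(per_turn):
        mean = float(np.mean(per_turn[key]))
        pos = mean >= BROAD_THRESHOLD
        labels.append(
            GoldLabel(
                conversation_id=key[0],
                turn_index=key[1],
                mean_score=mean,
                broad_positive=pos,
                proctcae_positive=pos,
            )
        )
    return labels


def apply_proctcae_overrides(
    gold: list[GoldLabel], overrides: dict[TurnKey, bool] | list[tuple[TurnKey, bool]]
) -> list[GoldLabel]:
    """Overlay manual PRO-CTCAE-relevance decisions on broad gold labels.

    Non-overridden turns keep ``proctcae_positive == broad_positive``.
    Idempotent: applying the same overrides twice equals applying once.
    Unknown turn keys raise.
    """
    ov = dict(overrides)
    known = {g.key for g in gold}
    unknown = sorted(set(ov) - known)
    if unknown:
        raise AnnotationError(f"override keys not in gold standard: {unknown[:10]}")
    out = []
    for g in gold:
        if g.key in ov:
            out.append(replace(g, proctcae_positive=bool(ov[g.key]), override_source="manual"))
        else:
            out.append(replace(g, proctcae_positive=g.broad_positive, override_source="none"))
    return out


# ---------------------------------------------------------------------------
# inter-rater reliability

def cohen_kappa(a: list[int], b: list[int]) -> float:
    """Cohen's kappa for two raters over paired labels (closed form)."""
    if len(a) != len(b) or not a:
        raise AnnotationError("paired label vectors of equal nonzero length required")
    n = len(a)
    po = sum(x == y for x, y in zip(a, b)) / n
    cats = set(a) | set(b)
    pe = sum((a.count(c) / n) * (b.count(c) / n) for c in cats)
    if pe >= 1.0:
        logger.warning("chance agreement is 1 (constant identical raters); kappa undefined")
        return float("nan")
    return (po - pe) / (1 - pe)


def fleiss_kappa(table: np.ndarray) -> float:
    """Fleiss' kappa from an items × categories count table (closed form).

    Each row must sum to the same number of raters r ≥ 2.
    """
    table = np.asarray(table, dtype=float)
    n, _ = table.shape
    r = table[0].sum()
    if not np.allclose(table.sum(axis=1), r) or r < 2:
        raise AnnotationError("Fleiss' kappa requires a fully crossed design (equal raters per item)")
    p_j = table.sum(axis=0) / (n * r)
    p_i = (np.square(table).sum(axis=1) - r) / (r * (r - 1))
    p_bar = p_i.mean()
    p_e = float(np.square(p_j).sum())
    if p_e >= 1.0:
        logger.warning("chance agreement is 1; Fleiss kappa undefined")
        return float("nan")
    return float((p_bar - p_e) / (1 - p_e))


def interrater_kappa(
    scores: list[CoderScore],
    binarize_at: float | None = BROAD_THRESHOLD,
    kind: str = "fleiss",
) -> ReliabilityReport:
    """Inter-rater reliability over the turns the coders share.

    ``binarize_at`` maps each 0–3 score to positive iff score ≥ threshold
    (pass ``None`` to agree on the raw ordinal scale).  ``kind``:

    * ``"cohen-pairwise-mean"`` — Cohen's kappa per coder pair over the turns
      both scored, averaged across pairs (pairs with undefined kappa are
      dropped with a warning);
    * ``"fleiss"`` — Fleiss' kappa over turns scored by every coder.
    """
    df = pd.DataFrame(
        [(s.conversation_id, s.turn_index, s.coder_id, s.score) for s in scores],
        columns=["conversation_id", "turn_index", "coder_id", "score"],
    )
    if df.empty or df["coder_id"].nunique() < 2:
        raise AnnotationError("reliability requires scores from at least 2 coders")
    if binarize_at is not None:
        df["label"] = (df["score"] >= binarize_at).astype(int)
    else:
        df["label"] = df["score"]
    wide = df.pivot_table(
        index=["conversation_id", "turn_index"], columns="coder_id",
        values="label", aggfunc="first",
    )
    coders = list(wide.columns)
    if kind == "cohen-pairwise-mean":
        kappas = []
        for c1, c2 in combinations(coders, 2):
            both = wide[[c1, c2]].dropna()
            if both.empty:
                continue
            k = cohen_kappa(list(both[c1].astype(int)), list(both[c2].astype(int)))
            if not math.isnan(k):
                kappas.append(k)
        if not kappas:
            logger.warning("no coder pair yields a defined kappa")
            kappa = float("nan")
        else:
            kappa = float(np.mean(kappas))
        used = wide.dropna(thresh=2)
    elif kind == "fleiss":
        used = wide.dropna()
        if used.empty:
            raise AnnotationError("Fleiss' kappa requires turns scored by every coder")
        values = sorted(df["label"].unique())
        table = np.zeros((len(used), len(values)))
        for j, v in enumerate(values):
            table[:, j] = (used.values == v).sum(axis=1)
        kappa = fleiss_kappa(table)
    else:
        raise AnnotationError(f"unknown kappa kind {kind!r}")
    return ReliabilityReport(
        n_conversations=used.index.get_level_values(0).nunique() if len(used) else 0,
        n_turns=len(used),
        n_coders=len(coders),
        kappa_statistic=kappa,
        kappa_kind=kind,
    )


# ---------------------------------------------------------------------------
# tabular I/O for scores and overrides

def read_scores(path) -> list[CoderScore]:
    """Read coder scores (columns: conversation_id, turn_index, coder_id, score)."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = {"conversation_id", "turn_index", "coder_id", "score"} - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    return [
        CoderScore(r.conversation_id, int(r.turn_index), r.coder_id, int(r.score))
        for r in df.itertuples()
    ]


def write_scores(scores: list[CoderScore], path) -> None:
    pd.DataFrame(
        [(s.conversation_id, s.turn_index, s.coder_id, s.score) for s in scores],
        columns=["conversation_id", "turn_index", "coder_id", "score"],
    ).to_csv(path, index=False)


def read_overrides(path) -> dict[TurnKey, bool]:
    """Read the PRO-CTCAE override sidecar (conversation_id, turn_index, proctcae_positive)."""
    df = pd.read_csv(path, comment="#", dtype=str, keep_default_na=False)
    missing = {"conversation_id", "turn_index", "proctcae_positive"} - set(df.columns)
    if missing:
        raise AnnotationError(f"{path}: missing columns {sorted(missing)}")
    truthy = {"true": True, "1": True, "yes": True, "false": False, "0": False, "no": False}
    return {
        (r.conversation_id, int(r.turn_index)): truthy[str(r.proctcae_positive).strip().lower()]
        for r in df.itertuples()
    }


def write_overrides(overrides: dict[TurnKey, bool], path, notes: dict[TurnKey, str] | None = None) -> None:
    notes = notes or {}
    pd.DataFrame(
        [
            (cid, ti, str(v).lower(), notes.get((cid, ti), ""))
            for (cid, ti), v in sorted(overrides.items())
        ],
        columns=["conversation_id", "turn_index", "proctcae_positive", "note"],
    ).to_csv(path, index=False)
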