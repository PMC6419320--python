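"""Scoring extraction output against gold-standard PT annotations.

The reference is a manually coded set of PT codes per drug per labeling
section.  Scoring is set-based at PT granularity: for each drug,
tp = |predicted ∩ gold|, fp = |predicted − gold|, fn = |gold − predicted|;
recall = tp/(tp+fn), precision = tp/(tp+fp).  Macro averages are
unweighted means over drugs.  A drug whose gold and predicted sets are
both empty scores recall = precision = 1.0 by convention (logged).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Set

from .matcher import ExtractionResult
from .meddra import Dictionary

logger = logging.getLogger(__name__)


class EvaluationError(Exception):
    pass


class AlignmentError(EvaluationError):
    """Gold annotations reference a drug with no extraction result."""


@dataclass(frozen=True)
class GoldAnnotation:
    set_id: str
    section_loinc: str
    pt_codes: frozenset

    def validate(self, d: Dictionary) -> None:
        unknown = {p for p in self.pt_codes if p not in d.pts}
        if unknown:
            raise EvaluationError(
                f"gold for {self.set_id}/{self.section_loinc} references "
                f"unknown PT codes {sorted(unknown)}"
            )


@dataclass(frozen=True)
class DrugScore:
    tp: int
    fp: int
    fn: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else 1.0

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else 1.0


@dataclass
class EvalResult:
    per_drug: Dict[str, DrugScore]
    macro_recall: float
    macro_precision: float
    n_perfect_recall: int


def read_gold_tsv(path: str) -> List[GoldAnnotation]:
    """Read gold rows ``set_id <tab> section_loinc <tab> pt_code``."""
    acc: Dict[tuple, Set[int]] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise EvaluationError(
                    f"{path}:{lineno}: expected 3 tab-separated fields"
                )
            try:
                pt = int(parts[2])
            except ValueError:
                raise EvaluationError(
                    f"{path}:{lineno}: PT code {parts[2]!r} is not an integer"
                ) from None
            acc.setdefault((parts[0], parts[1]), set()).add(pt)
    return [
        GoldAnnotation(set_id=k[0], section_loinc=k[1], pt_codes=frozenset(v))
        for k, v in sorted(acc.items())
    ]


def evaluate(
    results: Iterable[ExtractionResult],
    gold: Iterable[GoldAnnotation],
    section_loinc: str,
) -> EvalResult:
    """Score predictions against gold for one section.

    Every gold drug must have an extraction result; drugs without gold for
    the named section are treated as having an empty gold set only when
    they appear in the gold file for that section (drugs entirely absent
    from gold are not evaluated).
    """
    by_id = {r.set_id: r for r in results}
    gold_rows = [g for g in gold if g.section_loinc == section_loinc]
    missing = [g.set_id for g in gold_rows if g.set_id not in by_id]
    if missing:
        raise AlignmentError(
            f"gold references set_ids with no extraction result: {missing[:5]}"
        )

    per_drug: Dict[str, DrugScore] = {}
    for g in gold_rows:
        pred: Set[int] = set(by_id[g.set_id].per_section_pts.get(section_loinc, set()))
        gset = set(g.pt_codes)
        score = DrugScore(
            tp=len(pred & gset), fp=len(pred - gset), fn=len(gset - pred)
        )
        if not pred and not gset:
            logger.info(
                "drug %s has empty gold and empty prediction for %s; "
                "scored 1.0/1.0 by convention", g.set_id, section_loinc,
            )
        per_drug[g.set_id] = score

    if not per_drug:
        raise EvaluationError(f"no gold annotations for section {section_loinc!r}")
    n = len(per_drug)
    return EvalResult(
        per_drug=per_drug,
        macro_recall=sum(s.recall for s in per_drug.values()) / n,
        macro_precision=sum(s.precision for s in per_drug.values()) / n,
        n_perfect_recall=sum(1 for s in per_drug.values() if s.recall == 1.0),
    )
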