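"""Drug x PT x section occurrence matrix and descriptive ADR statistics.

The binary occurrence tensor (drug x PT x section, sections BW / WP / AR /
whole) is the substrate of every downstream statistic: per-section term
accounting, top-N most frequent PTs, cross-section top-N overlaps, and
per-PT section rates (share of section-bearing drugs that mention the PT).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_EVEN
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .matcher import ExtractionResult
from .spl import DEFAULT_LOINC_MAP, WHOLE, Corpus

logger = logging.getLogger(__name__)

SECTIONS = ("BW", "WP", "AR", WHOLE)


class OccurrenceError(Exception):
    pass


@dataclass
class DrugPTMatrix:
    """Binary drug x PT x section occurrence tensor.

    ``occurrence[d, p, s]`` is 1 when drug ``d`` mentions PT ``p`` in
    section ``s``; ``section_presence[d, s]`` (BW/WP/AR only) records
    whether the drug's label has that section at all.
    """

    set_ids: List[str]
    pt_codes: List[int]
    occurrence: np.ndarray          # (n_drugs, n_pts, 4) of {0,1}
    section_presence: np.ndarray    # (n_drugs, 3) bool, BW/WP/AR order
    pt_names: Dict[int, str] = field(default_factory=dict)
    section_llts: Dict[str, Set[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._drug_ix = {s: i for i, s in enumerate(self.set_ids)}
        self._pt_ix = {p: i for i, p in enumerate(self.pt_codes)}
        self._sec_ix = {s: i for i, s in enumerate(SECTIONS)}

    def section_slice(self, section: str) -> np.ndarray:
        try:
            return self.occurrence[:, :, self._sec_ix[section]]
        except KeyError:
            raise OccurrenceError(f"unknown section {section!r}") from None

    def section_pt_set(self, section: str) -> Set[int]:
        sl = self.section_slice(section)
        return {self.pt_codes[j] for j in np.flatnonzero(sl.any(axis=0))}

    def drugs_with_section(self, section: str) -> int:
        if section == WHOLE:
            return len(self.set_ids)
        return int(self.section_presence[:, self._sec_ix[section]].sum())

    def pt_label(self, pt_code: int) -> str:
        return self.pt_names.get(pt_code, str(pt_code))


def build_matrix(
    results: Iterable[ExtractionResult],
    corpus: Corpus,
    pt_names: Optional[Dict[int, str]] = None,
    loinc_map: Dict[str, str] = DEFAULT_LOINC_MAP,
) -> DrugPTMatrix:
    """Assemble the occurrence tensor from per-document extraction results.

    ``results`` must cover every corpus document; the PT axis is the union
    of PTs observed in any section.  LLT provenance (for per-section LLT
    counts) is retained when the extraction results carry matches.
    """
    by_id = {r.set_id: r for r in results}
    unknown = set(by_id) - {d.set_id for d in corpus.documents}
    if unknown:
        raise OccurrenceError(
            f"extraction results for unknown set_ids: {sorted(unknown)}"
        )
    missing = [d.set_id for d in corpus.documents if d.set_id not in by_id]
    if missing:
        raise OccurrenceError(
            f"missing extraction results for documents: {missing[:5]}"
        )

    sec_to_loinc = dict(loinc_map)
    pts: Set[int] = set()
    for r in by_id.values():
        for s in r.per_section_pts.values():
            pts.update(s)
    pt_codes = sorted(pts)
    pt_ix = {p: i for i, p in enumerate(pt_codes)}
    set_ids = [d.set_id for d in corpus.documents]

    occ = np.zeros((len(set_ids), len(pt_codes), len(SECTIONS)), dtype=np.uint8)
    presence = np.zeros((len(set_ids), 3), dtype=bool)
    section_llts: Dict[str, Set[int]] = {s: set() for s in SECTIONS}
    for i, doc in enumerate(corpus.documents):
        r = by_id[doc.set_id]
        for k, sec in enumerate(SECTIONS[:3]):
            presence[i, k] = sec_to_loinc[sec] in doc.sections
        for k, sec in enumerate(SECTIONS):
            loinc = sec_to_loinc.get(sec, WHOLE)
            for pt in r.per_section_pts.get(loinc, ()):  # absent section -> 0s
                occ[i, pt_ix[pt], k] = 1
            section_llts[sec].update(r.section_llts(loinc))

    return DrugPTMatrix(
        set_ids=set_ids,
        pt_codes=pt_codes,
        occurrence=occ,
        section_presence=presence,
        pt_names=dict(pt_names or {}),
        section_llts=section_llts,
    )


def _pct(numer: int, denom: int, places: int = 1) -> float:
    """Percentage rounded half-even to ``places`` decimals."""
    if denom == 0:
        return float("nan")
    q = Decimal(numer) * 100 / Decimal(denom)
    exp = Decimal(1).scaleb(-places)
    return float(q.quantize(exp, rounding=ROUND_HALF_EVEN))


def section_summary(m: DrugPTMatrix) -> pd.DataFrame:
    """Per-section accounting of distinct LLTs, distinct PTs and drugs.

    Mirrors a labeling-section occurrence table: one row per section plus
    the whole-document row, with each distinct-term count also expressed as
    a one-decimal percentage of the whole-document count.
    """
    whole_pts = len(m.section_pt_set(WHOLE))
    whole_llts = len(m.section_llts.get(WHOLE, set()))
    rows = []
    for sec in SECTIONS:
        n_pts = len(m.section_pt_set(sec))
        n_llts = len(m.section_llts.get(sec, set()))
        rows.append({
            "section": sec,
            "n_drugs": m.drugs_with_section(sec),
            "n_llts": n_llts,
            "llt_pct_of_whole": _pct(n_llts, whole_llts) if whole_llts else float("nan"),
            "n_pts": n_pts,
            "pt_pct_of_whole": _pct(n_pts, whole_pts) if whole_pts else float("nan"),
        })
    return pd.DataFrame(rows).set_index("section")


def top_n(m: DrugPTMatrix, section: str, n: int) -> List[Tuple[int, int]]:
    """Top ``n`` PTs of a section by drug count.

    Sorted by count descending; ties broken by PT name ascending (then by
    code, for reproducibility when names collide).  Returns
    ``[(pt_code, drug_count), ...]``; shorter than ``n`` when fewer PTs
    occur in the section.
    """
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    counts = m.section_slice(section).sum(axis=0)
    ranked = sorted(
        (
            (int(counts[j]), m.pt_label(p), p)
            for j, p in enumerate(m.pt_codes)
            if counts[j] > 0
        ),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    return [(p, c) for c, _, p in ranked[:n]]


def top_overlap(m: DrugPTMatrix, section_a: str, section_b: str, n: int) -> Set[int]:
    """PTs present in both sections' top-``n`` lists."""
    a = {p for p, _ in top_n(m, section_a, n)}
    b = {p for p, _ in top_n(m, section_b, n)}
    return a & b


@dataclass(frozen=True)
class SectionRate:
    """Exact rational PT-in-section rate with a 2-decimal percent view."""

    numerator: int
    denominator: int

    @property
    def fraction(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    @property
    def percent(self) -> float:
        return _pct(self.numerator, self.denominator, places=2)

    def __str__(self) -> str:
        return f"{self.numerator}/{self.denominator} ({self.percent:.2f}%)"


def pt_section_rate(m: DrugPTMatrix, pt_code: int, section: str) -> SectionRate:
    """Fraction of section-bearing drugs whose section mentions the PT."""
    denom = m.drugs_with_section(section)
    if denom == 0:
        raise OccurrenceError(f"no drug carries section {section!r}; rate undefined")
    if pt_code in m._pt_ix:
        numer = int(m.section_slice(section)[:, m._pt_ix[pt_code]].sum())
    else:
        numer = 0
    return SectionRate(numerator=numer, denominator=denom)
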