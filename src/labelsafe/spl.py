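"""Structured Product Labeling (SPL) parsing and corpus selection.

FDA drug labeling is distributed as HL7 SPL XML.  Each labeling section is
identified by a LOINC code; the three adverse-reaction-bearing sections are
Boxed Warning (34066-1), Warnings and Precautions (43685-7) and Adverse
Reactions (34084-4).  This module parses a pragmatic subset of the SPL
schema (set id, effective time, active ingredients, marketing category,
LOINC-coded sections) and applies the four sequential corpus-selection
criteria used to define a study set of single-ingredient NDA drugs:

I.   human prescription drug (over-the-counter labels removed);
II.  New Drug Application (NDA) approval pathway;
III. single active-ingredient UNII;
IV.  most recent label per UNII (latest effective date; ties broken by the
     lexicographically greater set id, with a warning).
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import os
import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Union

from lxml import etree

logger = logging.getLogger(__name__)

#: Canonical section-name -> LOINC code map.  The AR code is the standard
#: SPL assignment for the Adverse Reactions section.
DEFAULT_LOINC_MAP = {"BW": "34066-1", "WP": "43685-7", "AR": "34084-4"}

#: Pseudo-section meaning "all sections concatenated in document order".
WHOLE = "whole"

_LOINC_RE = re.compile(r"^\d+-\d$")

APPLICATION_TYPES = ("NDA", "ANDA", "BLA", "OTC", "other")


class SplError(Exception):
    pass


class SplParseError(SplError):
    """The XML could not be parsed."""


class SplMetadataError(SplError):
    """A required metadata field is missing; the message names the field."""


@dataclass(frozen=True)
class LabelSection:
    loinc_code: str
    title: str
    text: str


@dataclass
class LabelDocument:
    """One drug's labeling: LOINC-keyed sections plus selection metadata."""

    set_id: str
    unii: str
    ingredient_count: int
    application_type: str
    effective_date: Optional[_dt.date]
    sections: Dict[str, LabelSection]

    def whole_text(self) -> str:
        """All section texts concatenated in document order."""
        return " ".join(s.text for s in self.sections.values() if s.text)


@dataclass
class Corpus:
    documents: List[LabelDocument]
    selection_log: Dict[str, int] = field(default_factory=dict)


def _local(el) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def _iter_local(root, name: str):
    for el in root.iter():
        if _local(el) == name:
            yield el


def _classify_application(display: str) -> str:
    name = display.strip().upper()
    if name == "NDA":
        return "NDA"
    if name == "ANDA":
        return "ANDA"
    if name == "BLA":
        return "BLA"
    if name.startswith("OTC"):
        return "OTC"
    return "other"


def _normalize_ws(text: str) -> str:
    return " ".join(text.split())


def parse_spl(xml_source: Union[str, bytes]) -> LabelDocument:
    """Parse one SPL document from a file path, XML text, or bytes.

    Section text is the whitespace-normalized concatenation of all text
    nodes under the section's ``<text>`` content, in document order (table
    cells included); nested subsections are folded into their LOINC-coded
    ancestor.  Repeated sections with the same LOINC code are concatenated.
    """
    try:
        if isinstance(xml_source, bytes):
            root = etree.fromstring(xml_source)
        elif isinstance(xml_source, str) and xml_source.lstrip().startswith("<"):
            root = etree.fromstring(xml_source.encode("utf-8"))
        else:
            root = etree.parse(str(xml_source)).getroot()
    except (etree.XMLSyntaxError, OSError) as exc:
        raise SplParseError(f"cannot parse SPL XML: {exc}") from exc

    set_id = None
    for el in _iter_local(root, "setId"):
        set_id = el.get("root")
        break
    if not set_id:
        raise SplMetadataError("missing metadata field: set_id")

    effective_date: Optional[_dt.date] = None
    for el in root:
        if _local(el) == "effectiveTime" and el.get("value"):
            raw = el.get("value")[:8]
            try:
                effective_date = _dt.datetime.strptime(raw, "%Y%m%d").date()
            except ValueError:
                raise SplMetadataError(
                    f"unparseable effective_date value {raw!r}"
                ) from None
            break

    uniis: List[str] = []
    for ing in _iter_local(root, "ingredient"):
        cls = (ing.get("classCode") or "").upper()
        if cls and not cls.startswith("ACTI"):
            continue  # inactive ingredient
        for sub in ing.iter():
            if _local(sub) == "code" and sub.get("code"):
                uniis.append(sub.get("code"))
                break
    if not uniis:
        raise SplMetadataError("missing metadata field: unii")

    application_type = "other"
    for appr in _iter_local(root, "approval"):
        for code in appr.iter():
            if _local(code) == "code":
                application_type = _classify_application(
                    code.get("displayName") or code.get("code") or ""
                )
                break
        break

    sections: Dict[str, LabelSection] = {}
    for sec in _iter_local(root, "section"):
        # fold nested subsections into their coded ancestor
        anc = sec.getparent()
        nested = False
        while anc is not None:
            if _local(anc) == "section":
                nested = True
                break
            anc = anc.getparent()
        if nested:
            continue
        loinc = None
        title = ""
        for child in sec:
            name = _local(child)
            if name == "code" and child.get("code"):
                loinc = child.get("code")
            elif name == "title":
                title = _normalize_ws("".join(child.itertext()))
        if loinc is None or not _LOINC_RE.match(loinc):
            continue
        chunks = [
            _normalize_ws(" ".join(t.itertext())) for t in _iter_local(sec, "text")
        ]
        text = _normalize_ws(" ".join(c for c in chunks if c))
        if loinc in sections:
            prev = sections[loinc]
            text = _normalize_ws(prev.text + " " + text)
            title = prev.title or title
        sections[loinc] = LabelSection(loinc_code=loinc, title=title, text=text)

    return LabelDocument(
        set_id=set_id,
        unii=uniis[0],
        ingredient_count=len(uniis),
        application_type=application_type,
        effective_date=effective_date,
        sections=sections,
    )


def select_corpus(documents: Iterable[LabelDocument]) -> Corpus:
    """Apply selection criteria I-IV in order; log per-criterion exclusions.

    The selection log keys are ``I_not_prescription``, ``II_not_nda``,
    ``III_multi_ingredient``, ``IV_missing_date`` and ``IV_duplicate_unii``;
    their sum plus the survivor count equals the input count.
    """
    docs = list(documents)
    log = {
        "I_not_prescription": 0,
        "II_not_nda": 0,
        "III_multi_ingredient": 0,
        "IV_missing_date": 0,
        "IV_duplicate_unii": 0,
    }

    stage1 = []
    for d in docs:
        if d.application_type in ("OTC", "other"):
            log["I_not_prescription"] += 1
        else:
            stage1.append(d)

    stage2 = []
    for d in stage1:
        if d.application_type != "NDA":
            log["II_not_nda"] += 1
        else:
            stage2.append(d)

    stage3 = []
    for d in stage2:
        if d.ingredient_count != 1:
            log["III_multi_ingredient"] += 1
        else:
            stage3.append(d)

    by_unii: Dict[str, List[LabelDocument]] = {}
    order: List[str] = []
    for d in stage3:
        if d.effective_date is None:
            log["IV_missing_date"] += 1
            logger.warning("document %s lacks an effective date; excluded", d.set_id)
            continue
        if d.unii not in by_unii:
            order.append(d.unii)
        by_unii.setdefault(d.unii, []).append(d)

    survivors: List[LabelDocument] = []
    for unii in order:
        group = by_unii[unii]
        best = max(group, key=lambda d: (d.effective_date, d.set_id))
        ties = [
            d for d in group
            if d is not best and d.effective_date == best.effective_date
        ]
        if ties:
            logger.warning(
                "UNII %s has %d documents sharing effective date %s; "
                "kept set_id %s (lexicographic tie-break)",
                unii, len(ties) + 1, best.effective_date, best.set_id,
            )
        log["IV_duplicate_unii"] += len(group) - 1
        survivors.append(best)

    return Corpus(documents=survivors, selection_log=log)


# -- JSONL serialization ---------------------------------------------------

def document_to_dict(d: LabelDocument) -> dict:
    return {
        "set_id": d.set_id,
        "unii": d.unii,
        "ingredient_count": d.ingredient_count,
        "application_type": d.application_type,
        "effective_date": d.effective_date.isoformat() if d.effective_date else None,
        "sections": {
            c: {"title": s.title, "text": s.text} for c, s in d.sections.items()
        },
    }


def document_from_dict(obj: dict) -> LabelDocument:
    date = obj.get("effective_date")
    return LabelDocument(
        set_id=obj["set_id"],
        unii=obj["unii"],
        ingredient_count=obj["ingredient_count"],
        application_type=obj["application_type"],
        effective_date=_dt.date.fromisoformat(date) if date else None,
        sections={
            c: LabelSection(loinc_code=c, title=s.get("title", ""), text=s["text"])
            for c, s in obj["sections"].items()
        },
    )


def write_corpus_jsonl(corpus: Corpus, path: str) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for d in corpus.documents:
            fh.write(json.dumps(document_to_dict(d)) + "\n")


def read_corpus_jsonl(path: str) -> Corpus:
    docs = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.strip():
                docs.append(document_from_dict(json.loads(line)))
    return Corpus(documents=docs, selection_log={})
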