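"""MedDRA-style hierarchical terminology: loading, validation, roll-up.

The terminology is a strict three-level hierarchy as used for adverse-event
coding: granular Low Level Terms (LLTs) group under a single Preferred Term
(PT), and each PT carries one *primary* System Organ Class (SOC).  Analyses
of adverse-reaction profiles roll label mentions up LLT -> PT -> primary SOC.
Five SOCs that do not describe medical disorders (Investigations, Injury,
Social circumstances, Surgical procedures, Product issues) are conventionally
excluded from ADR statistics; the remaining "disorder" SOCs are tracked in
:attr:`Dictionary.disorder_soc_codes`.

Files use the standard MedDRA ASCII distribution dialect: "$"-delimited
fields, no quoting, trailing empty fields permitted, one record per line.
Column positions match the real ``llt.asc`` / ``pt.asc`` / ``soc.asc`` files
so that licensed MedDRA distributions drop in unchanged.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

LEVELS = ("LLT", "PT", "SOC")

#: Default names of the five SOCs excluded from disorder-level ADR analysis.
DEFAULT_EXCLUDED_SOC_NAMES = (
    "Injury, poisoning and procedural complications",
    "Investigations",
    "Social circumstances",
    "Surgical and medical procedures",
    "Product issues",
)


class DictionaryError(Exception):
    """Base class for terminology errors."""


class DictionaryParseError(DictionaryError):
    """A distribution file line could not be parsed."""


class DictionaryIntegrityError(DictionaryError):
    """The loaded hierarchy violates a structural invariant."""


class TermLookupError(DictionaryError, KeyError):
    """A code was queried that is not present at the expected level."""


@dataclass(frozen=True)
class TermRecord:
    """One term at one hierarchy level.

    ``parent_pt_code`` is set for LLTs only, ``primary_soc_code`` for PTs
    only, ``soc_abbrev`` for SOCs only (e.g. ``"Nerv"``, ``"Vasc"``).
    """

    code: int
    name: str
    level: str
    parent_pt_code: Optional[int] = None
    primary_soc_code: Optional[int] = None
    soc_abbrev: Optional[str] = None

    def __post_init__(self) -> None:
        if self.level not in LEVELS:
            raise ValueError(f"unknown level {self.level!r}")
        if not self.name:
            raise ValueError(f"term {self.code} has an empty name")


@dataclass(frozen=True)
class Dictionary:
    """An immutable, validated LLT/PT/SOC hierarchy.

    ``disorder_soc_codes`` holds the SOC codes retained for ADR analysis
    (all SOCs minus the configured excluded names).
    """

    llts: Mapping[int, TermRecord]
    pts: Mapping[int, TermRecord]
    socs: Mapping[int, TermRecord]
    disorder_soc_codes: frozenset = field(default_factory=frozenset)

    # -- roll-up queries ---------------------------------------------------
    def llt_to_pt(self, llt_code: int) -> int:
        """Return the unique parent PT code of an LLT."""
        try:
            return self.llts[llt_code].parent_pt_code  # type: ignore[return-value]
        except KeyError:
            raise TermLookupError(f"unknown LLT code {llt_code}") from None

    def pt_primary_soc(self, pt_code: int) -> int:
        """Return the single primary SOC code of a PT.

        Multi-axial links beyond the primary SOC are not modeled.
        """
        try:
            return self.pts[pt_code].primary_soc_code  # type: ignore[return-value]
        except KeyError:
            raise TermLookupError(f"unknown PT code {pt_code}") from None

    def pt_name(self, pt_code: int) -> str:
        try:
            return self.pts[pt_code].name
        except KeyError:
            raise TermLookupError(f"unknown PT code {pt_code}") from None

    def soc_name(self, soc_code: int) -> str:
        try:
            return self.socs[soc_code].name
        except KeyError:
            raise TermLookupError(f"unknown SOC code {soc_code}") from None

    def is_disorder_pt(self, pt_code: int) -> bool:
        """True if the PT's primary SOC is one of the disorder SOCs."""
        return self.pt_primary_soc(pt_code) in self.disorder_soc_codes

    def validate(self) -> None:
        """Check referential integrity; raise :class:`DictionaryIntegrityError`."""
        dangling = []
        for llt in self.llts.values():
            if llt.parent_pt_code not in self.pts:
                dangling.append(f"LLT {llt.code} -> PT {llt.parent_pt_code}")
        for pt in self.pts.values():
            if pt.primary_soc_code not in self.socs:
                dangling.append(f"PT {pt.code} -> SOC {pt.primary_soc_code}")
        if dangling:
            raise DictionaryIntegrityError(
                "dangling parent references: " + "; ".join(dangling)
            )
        if not self.disorder_soc_codes <= set(self.socs):
            raise DictionaryIntegrityError("disorder_soc_codes outside SOC table")


def _read_records(path: str, min_fields: int, label: str):
    """Yield (lineno, fields) from a '$'-delimited ASCII file."""
    with open(path, "r", encoding="ascii", errors="strict") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("$")
            if len(fields) < min_fields:
                raise DictionaryParseError(
                    f"{path}:{lineno}: expected >= {min_fields} '$'-fields "
                    f"in {label} record, got {len(fields)}"
                )
            yield lineno, fields


def _parse_code(raw: str, path: str, lineno: int, what: str) -> int:
    try:
        return int(raw)
    except ValueError:
        raise DictionaryParseError(
            f"{path}:{lineno}: {what} {raw!r} is not an integer"
        ) from None


def load_dictionary(
    llt_path: str,
    pt_path: str,
    soc_path: str,
    excluded_soc_names: Sequence[str] = DEFAULT_EXCLUDED_SOC_NAMES,
) -> Dictionary:
    """Load a MedDRA-style ASCII distribution.

    Field layout (matching the licensed distribution):

    * ``soc`` file: ``soc_code $ soc_name $ soc_abbrev``
    * ``pt`` file:  ``pt_code $ pt_name $ <legacy null> $ pt_soc_code``
    * ``llt`` file: ``llt_code $ llt_name $ pt_code``

    ``excluded_soc_names`` selects, by name, SOCs dropped from
    ``disorder_soc_codes`` (defaults to the five non-disorder SOCs).
    """
    socs: dict[int, TermRecord] = {}
    for lineno, f in _read_records(soc_path, 3, "SOC"):
        code = _parse_code(f[0], soc_path, lineno, "SOC code")
        if code in socs:
            raise DictionaryIntegrityError(f"duplicate SOC code {code}")
        socs[code] = TermRecord(code=code, name=f[1], level="SOC", soc_abbrev=f[2])

    pts: dict[int, TermRecord] = {}
    for lineno, f in _read_records(pt_path, 4, "PT"):
        code = _parse_code(f[0], pt_path, lineno, "PT code")
        soc_code = _parse_code(f[3], pt_path, lineno, "PT primary SOC code")
        if code in pts:
            raise DictionaryIntegrityError(f"duplicate PT code {code}")
        pts[code] = TermRecord(
            code=code, name=f[1], level="PT", primary_soc_code=soc_code
        )

    llts: dict[int, TermRecord] = {}
    for lineno, f in _read_records(llt_path, 3, "LLT"):
        code = _parse_code(f[0], llt_path, lineno, "LLT code")
        pt_code = _parse_code(f[2], llt_path, lineno, "LLT parent PT code")
        if code in llts:
            raise DictionaryIntegrityError(f"duplicate LLT code {code}")
        llts[code] = TermRecord(
            code=code, name=f[1], level="LLT", parent_pt_code=pt_code
        )

    excluded = {n.casefold() for n in excluded_soc_names}
    disorder = frozenset(
        c for c, rec in socs.items() if rec.name.casefold() not in excluded
    )
    d = Dictionary(llts=llts, pts=pts, socs=socs, disorder_soc_codes=disorder)
    d.validate()
    logger.info(
        "loaded dictionary: %d LLTs, %d PTs, %d SOCs (%d disorder)",
        len(llts), len(pts), len(socs), len(disorder),
    )
    return d


def write_dictionary(d: Dictionary, out_dir: str) -> dict:
    """Write ``llt.asc``/``pt.asc``/``soc.asc`` in the ASCII dialect.

    Returns the mapping of table name to file path.  Round-trips through
    :func:`load_dictionary`.
    """
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "llt": os.path.join(out_dir, "llt.asc"),
        "pt": os.path.join(out_dir, "pt.asc"),
        "soc": os.path.join(out_dir, "soc.asc"),
    }
    with open(paths["soc"], "w", encoding="ascii") as fh:
        for rec in sorted(d.socs.values(), key=lambda r: r.code):
            fh.write(f"{rec.code}${rec.name}${rec.soc_abbrev}$\n")
    with open(paths["pt"], "w", encoding="ascii") as fh:
        for rec in sorted(d.pts.values(), key=lambda r: r.code):
            fh.write(f"{rec.code}${rec.name}$${rec.primary_soc_code}$\n")
    with open(paths["llt"], "w", encoding="ascii") as fh:
        for rec in sorted(d.llts.values(), key=lambda r: r.code):
            fh.write(f"{rec.code}${rec.name}${rec.parent_pt_code}$\n")
    return paths


def llt_to_pt(d: Dictionary, llt_code: int) -> int:
    """Functional alias for :meth:`Dictionary.llt_to_pt`."""
    return d.llt_to_pt(llt_code)


def pt_primary_soc(d: Dictionary, pt_code: int) -> int:
    """Functional alias for :meth:`Dictionary.pt_primary_soc`."""
    return d.pt_primary_soc(pt_code)
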