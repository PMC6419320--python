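"""Dictionary-based named-entity matcher for adverse-reaction terms.

The engine mirrors the behavior of classic full-text indexing engines used
for pharmacovigilance term extraction: text and dictionary terms are
lowercased, tokenized on non-alphanumerics, stop words are removed and the
remaining tokens stemmed; a label section matches an LLT when the section's
normalized token stream contains the LLT's normalized token sequence
contiguously.  Matched LLTs roll up to PTs and each PT is counted at most
once per section per document.

Two match policies are offered:

* ``all_matches`` ("oracle-compat", the default): every dictionary entry
  matching at any position is reported, including entries nested inside
  longer matches ("myocardial infarction" also yields "infarction") and
  whole collision groups of terms that normalize identically after
  stop-word removal ("Hepatitis", "Hepatitis A", "Hepatitis D").  This is
  the high-recall / low-precision regime.
* ``longest_match``: at each position only the longest entry wins and
  scanning resumes after it, suppressing nested false positives.

Both policies miss terms whose words appear non-contiguously in the text
("suicidal thinking and behavior" does not match "suicidal behavior") —
the documented false-negative mode of contiguous dictionary matching.
"""

from __future__ import annotations

import logging
import re
import unicodedata
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

from .meddra import Dictionary
from .spl import DEFAULT_LOINC_MAP, WHOLE, LabelDocument

logger = logging.getLogger(__name__)

#: Small fixed English stop list applied to both dictionary terms and text.
#: Includes the single-letter stop words that make "Hepatitis A" /
#: "Hepatitis D" index identically to "Hepatitis".
DEFAULT_STOP_WORDS = frozenset(
    """a an and are as at be been by d for in is it its of on or s t that
    the this to was were with""".split()
)

MATCH_POLICIES = ("all_matches", "longest_match")


class MatcherError(Exception):
    pass


class MatcherConfigError(MatcherError):
    pass


@dataclass(frozen=True)
class MatchConfig:
    stop_words: FrozenSet[str] = DEFAULT_STOP_WORDS
    stemming: bool = True
    match_policy: str = "all_matches"
    case_fold: bool = True

    def __post_init__(self) -> None:
        if self.match_policy not in MATCH_POLICIES:
            raise MatcherConfigError(f"unknown match policy {self.match_policy!r}")
        if any(w != w.lower() for w in self.stop_words):
            raise MatcherConfigError("stop words must be lowercase")


@dataclass(frozen=True)
class Token:
    text: str      # normalized token
    begin: int     # 0-based, half-open span into the raw text
    end: int


@dataclass(frozen=True)
class TermMatch:
    llt_code: int
    pt_code: int
    section_loinc: str
    begin: int
    end: int
    matched_surface: str


@dataclass
class ExtractionResult:
    """Per-document extraction: deduplicated PT sets with provenance."""

    set_id: str
    per_section_pts: Dict[str, Set[int]]
    matches: List[TermMatch] = field(default_factory=list)

    def section_llts(self, section: str) -> Set[int]:
        return {m.llt_code for m in self.matches if m.section_loinc == section}


# -- Porter stemmer --------------------------------------------------------
# Self-contained implementation of the classic Porter (1980) suffix
# stripper; applied identically to dictionary terms and label text, so any
# consistent English stemmer would serve.

_VOWELS = "aeiou"


def _is_cons(word: str, i: int) -> bool:
    ch = word[i]
    if ch in _VOWELS:
        return False
    if ch == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in the [C](VC)^m[V] decomposition."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        cons = _is_cons(stem, i)
        if cons and prev_vowel:
            m += 1
        prev_vowel = not cons
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (
        len(word) >= 2
        and word[-1] == word[-2]
        and _is_cons(word, len(word) - 1)
    )


def _cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    if not (
        _is_cons(word, len(word) - 3)
        and not _is_cons(word, len(word) - 2)
        and _is_cons(word, len(word) - 1)
    ):
        return False
    return word[-1] not in "wxy"


_STEP2 = [
    ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
    ("izer", "ize"), ("abli", "able"), ("alli", "al"), ("entli", "ent"),
    ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
    ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
    ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
]

_STEP3 = [
    ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
    ("ical", "ic"), ("ful", ""), ("ness", ""),
]

_STEP4 = [
    "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
    "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
]


def porter_stem(word: str) -> str:
    """Stem one lowercase token."""
    w = word
    if len(w) <= 2:
        return w

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w = w[:-2]
            flag = True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w = w[:-3]
            flag = True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and not w.endswith(("l", "s", "z")):
                w = w[:-1]
            elif _measure(w) == 1 and _cvc(w):
                w += "e"

    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    if len(w) > 0:
        for suf, rep in _STEP2:
            if w.endswith(suf):
                stem = w[: -len(suf)]
                if _measure(stem) > 0:
                    w = stem + rep
                break

    # step 3
    for suf, rep in _STEP3:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 0:
                w = stem + rep
            break

    # step 4
    for suf in _STEP4:
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if suf == "ion" and not stem.endswith(("s", "t")):
                continue
            if _measure(stem) > 1:
                w = stem
            break

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _cvc(stem)):
            w = stem

    # step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w


# -- normalization ---------------------------------------------------------

_TOKEN_RE = re.compile(r"[0-9A-Za-zÀ-ɏ]+")


def _fold(token: str) -> str:
    """Lowercase and Unicode-compatibility-fold one raw token."""
    token = token.casefold()
    decomposed = unicodedata.normalize("NFKD", token)
    return "".join(c for c in decomposed if not unicodedata.combining(c))


def normalize(text: str, cfg: MatchConfig = MatchConfig()) -> List[Token]:
    """Tokenize, fold, drop stop words, stem; keep raw-text spans.

    Tokens are maximal runs of letters/digits (hyphens and slashes split).
    Spans are 0-based half-open offsets into the raw input.
    """
    out: List[Token] = []
    for m in _TOKEN_RE.finditer(text):
        tok = _fold(m.group()) if cfg.case_fold else m.group()
        if tok in cfg.stop_words:
            continue
        if cfg.stemming:
            tok = porter_stem(tok)
        out.append(Token(text=tok, begin=m.start(), end=m.end()))
    return out


# -- index -----------------------------------------------------------------

@dataclass
class TermIndex:
    """Normalized LLT token sequence -> colliding LLT codes."""

    entries: Dict[Tuple[str, ...], FrozenSet[int]]
    lengths: Tuple[int, ...]  # distinct entry lengths, descending

    def collision_groups(self) -> Dict[Tuple[str, ...], FrozenSet[int]]:
        return {k: v for k, v in self.entries.items() if len(v) > 1}


def build_index(d: Dictionary, cfg: MatchConfig = MatchConfig()) -> TermIndex:
    """Index every LLT by its normalized token sequence.

    Distinct LLTs whose names normalize identically (e.g. "Hepatitis",
    "Hepatitis A", "Hepatitis D" under single-letter stop words) share one
    entry — the documented collision behavior.  LLTs normalizing to the
    empty sequence are excluded with a warning.
    """
    entries: Dict[Tuple[str, ...], Set[int]] = {}
    for llt in d.llts.values():
        key = tuple(t.text for t in normalize(llt.name, cfg))
        if not key:
            logger.warning(
                "LLT %d %r normalizes to the empty sequence; excluded",
                llt.code, llt.name,
            )
            continue
        entries.setdefault(key, set()).add(llt.code)
    frozen = {k: frozenset(v) for k, v in entries.items()}
    lengths = tuple(sorted({len(k) for k in frozen}, reverse=True))
    n_coll = sum(1 for v in frozen.values() if len(v) > 1)
    if n_coll:
        logger.info("term index has %d collision groups", n_coll)
    return TermIndex(entries=frozen, lengths=lengths)


# -- extraction ------------------------------------------------------------

def _scan(tokens: Sequence[Token], index: TermIndex, policy: str):
    """Yield (start_token, end_token, llt_codes) for contiguous index hits."""
    keys = index.entries
    n = len(tokens)
    texts = [t.text for t in tokens]
    if policy == "all_matches":
        for i in range(n):
            for L in index.lengths:
                if i + L > n:
                    continue
                key = tuple(texts[i:i + L])
                hit = keys.get(key)
                if hit:
                    yield i, i + L, hit
    else:  # longest_match
        i = 0
        while i < n:
            advanced = False
            for L in index.lengths:  # descending: longest wins
                if i + L > n:
                    continue
                hit = keys.get(tuple(texts[i:i + L]))
                if hit:
                    yield i, i + L, hit
                    i += L
                    advanced = True
                    break
            if not advanced:
                i += 1


def extract_terms(
    doc: LabelDocument,
    index: TermIndex,
    d: Dictionary,
    cfg: MatchConfig = MatchConfig(),
    section_codes: Sequence[str] = (),
) -> ExtractionResult:
    """Extract deduplicated PT sets per section (plus the ``whole`` pseudo-
    section), dropping PTs whose primary SOC is not a disorder SOC.

    ``section_codes`` defaults to the three ADR sections plus ``whole``.
    """
    if not section_codes:
        section_codes = tuple(DEFAULT_LOINC_MAP.values()) + (WHOLE,)
    known = set(DEFAULT_LOINC_MAP.values()) | {WHOLE} | set(doc.sections)
    for code in section_codes:
        if code not in known:
            raise MatcherConfigError(f"unknown section code {code!r}")

    per_section: Dict[str, Set[int]] = {}
    matches: List[TermMatch] = []
    dropped: Set[int] = set()
    for code in section_codes:
        if code == WHOLE:
            raw = doc.whole_text()
        else:
            sec = doc.sections.get(code)
            raw = sec.text if sec else ""
        pts: Set[int] = set()
        tokens = normalize(raw, cfg)
        for i, j, llt_codes in _scan(tokens, index, cfg.match_policy):
            begin, end = tokens[i].begin, tokens[j - 1].end
            for llt_code in sorted(llt_codes):
                pt_code = d.llt_to_pt(llt_code)
                if pt_code not in d.pts or not d.is_disorder_pt(pt_code):
                    dropped.add(pt_code)
                    continue
                pts.add(pt_code)
                matches.append(TermMatch(
                    llt_code=llt_code,
                    pt_code=pt_code,
                    section_loinc=code,
                    begin=begin,
                    end=end,
                    matched_surface=raw[begin:end],
                ))
        per_section[code] = pts
    if dropped:
        logger.debug(
            "dropped %d PTs whose primary SOC is excluded: %s",
            len(dropped), sorted(dropped),
        )
    return ExtractionResult(
        set_id=doc.set_id, per_section_pts=per_section, matches=matches
    )
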