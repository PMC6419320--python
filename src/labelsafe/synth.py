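"""Synthetic dictionaries, labeled corpora and gold annotations.

Licensed terminology and the FDA labeling snapshot cannot be redistributed,
so every pipeline stage is exercised on generated data with known ground
truth.  The generator emulates the statistical structure the analysis
assumes:

* a hierarchical dictionary of coined terms (synonymous LLTs under PTs,
  PTs under primary SOCs, disorder plus excluded SOCs);
* labeling whose ADR sections embed verbatim LLT surface forms in filler
  prose, with section-dependent mention density (Boxed Warning sparse,
  Adverse Reactions dense) and a configurable fraction of labels carrying
  a Boxed Warning;
* an optional enriched SOC whose PTs are oversampled in Boxed Warnings;
* ATC blocks of drugs sharing planted Boxed-Warning PT profiles;
* the documented matcher failure modes: stop-word-bearing term families
  ("Hepatitis" / "Hepatitis A" / "Hepatitis D"), nested term pairs
  ("Infarction" inside "Myocardial infarction"), and reworded mentions
  whose words are split non-contiguously, which a contiguous matcher must
  miss.

Filler vocabulary is a fixed word list disjoint (after normalization) from
every dictionary token, so known-answer tests are exact.  All sampling
goes through one seeded NumPy generator; a fixed seed reproduces the
outputs byte-for-byte.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import os
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .atc import ATCMap, write_atc_tsv
from .evaluation import GoldAnnotation
from .matcher import DEFAULT_STOP_WORDS, MatchConfig, normalize
from .meddra import (
    DEFAULT_EXCLUDED_SOC_NAMES,
    Dictionary,
    TermRecord,
    write_dictionary,
)
from .occurrence import SECTIONS, DrugPTMatrix
from .spl import DEFAULT_LOINC_MAP, Corpus, LabelDocument, LabelSection

logger = logging.getLogger(__name__)

#: Fixed filler vocabulary (classic typesetting filler): disjoint from the
#: stop list and, by construction, from all dictionary term tokens.
FILLER_WORDS = (
    "lorem ipsum dolor amet consectetur adipiscing elit eiusmod tempor "
    "incididunt labore dolore magna aliqua enim minim veniam nostrud "
    "ullamco laboris nisi aliquip commodo consequat duis aute irure "
    "reprehenderit voluptate velit esse cillum fugiat nulla pariatur "
    "excepteur sint occaecat cupidatat proident sunt culpa officia "
    "deserunt mollit anim laborum perspiciatis unde omnis iste natus"
).split()

_SYLLABLES = (
    "ba be bi bo bu da de di do du fa fe fi fo fu ga ge gi go gu ka ke ki "
    "ko ku la le li lo lu ma me mi mo mu na ne ni no nu pa pe pi po pu ra "
    "re ri ro ru sa se si so su ta te ti to tu va ve vi vo vu za ze zi zo zu"
).split()

_CODES = {"SOC": 10_000_001, "PT": 20_000_001, "LLT": 30_000_001}


@dataclass(frozen=True)
class FailureModes:
    """Which documented matcher failure modes to plant."""

    stopword_terms: bool = False
    nested_terms: bool = False
    reworded_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.reworded_rate <= 1.0:
            raise ValueError("reworded_rate must be in [0,1]")


@dataclass(frozen=True)
class AtcBlock:
    """A set of ATC classes whose drugs share one Boxed-Warning PT profile."""

    atc_codes: Tuple[str, ...]
    n_shared_pts: int


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for the synthetic corpus.

    Defaults mirror the observed structure of the NDA labeling corpus the
    analysis targets: 1164 single-ingredient drugs, 31.5% with a Boxed
    Warning and ~99% with Warnings-and-Precautions / Adverse-Reactions
    sections, a ~300-PT disorder universe (22 disorder SOCs x 13 PTs plus
    the 5 excluded SOCs), and mean planted mention counts increasing
    BW < WP < AR (severity decreases, coverage increases, in that order).
    """

    seed: int = 0
    n_socs: int = 22
    n_excluded_socs: int = 5
    n_pts_per_soc: int = 13
    n_llts_per_pt: int = 2
    n_drugs: int = 1164
    bw_fraction: float = 0.315
    wp_fraction: float = 0.986
    ar_fraction: float = 0.990
    section_rates: Tuple[float, float, float] = (2.0, 6.0, 12.0)  # BW, WP, AR
    enriched_soc: Optional[int] = None        # index into disorder SOC list
    enrichment_multiplier: float = 5.0
    n_atc_groups: int = 25
    multi_atc_rate: float = 0.10
    atc_blocks: Tuple[AtcBlock, ...] = ()
    failure_modes: FailureModes = FailureModes()

    def __post_init__(self) -> None:
        if min(self.section_rates) < 1.0:
            raise ValueError("section rates must be >= 1 (every present "
                             "ADR section mentions at least one term)")
        if not (self.section_rates[0] < self.section_rates[1]
                < self.section_rates[2]):
            raise ValueError("section rates must increase BW < WP < AR")
        if self.enrichment_multiplier < 1.0:
            raise ValueError("enrichment multiplier must be >= 1")
        for frac in (self.bw_fraction, self.wp_fraction, self.ar_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("section fractions must be in [0,1]")


@dataclass
class GroundTruth:
    """Everything the generator planted, for exact known-answer checks."""

    planted: Dict[str, Dict[str, Set[int]]]          # set_id -> loinc -> PTs
    unmatchable: List[Tuple[str, str, int]]           # (set_id, loinc, pt)
    enriched_soc_code: Optional[int]
    atc_partition: Dict[str, int]                     # atc code -> block id
    special_pts: Dict[str, int]                       # name -> pt code


@dataclass
class CorpusBundle:
    documents: List[LabelDocument]
    xml_by_set_id: Dict[str, str]
    gold: List[GoldAnnotation]
    atc: ATCMap
    ground_truth: GroundTruth


# -- word coinage ----------------------------------------------------------

class _WordForge:
    """Coin unique pronounceable words whose normalized (stemmed) forms are
    unique dictionary-wide and disjoint from filler and stop words."""

    def __init__(self, rng: np.random.Generator, extra_reserved: Sequence[str] = ()):
        cfg = MatchConfig()
        self._rng = rng
        self._cfg = cfg
        self._used: Set[str] = set()
        for w in list(FILLER_WORDS) + list(DEFAULT_STOP_WORDS) + list(extra_reserved):
            self._used.update(t.text for t in normalize(w, cfg))

    def reserve(self, name: str) -> None:
        self._used.update(t.text for t in normalize(name, self._cfg))

    def coin(self) -> str:
        for _ in range(1000):
            k = int(self._rng.integers(3, 5))
            idx = self._rng.integers(0, len(_SYLLABLES), size=k)
            word = "".join(_SYLLABLES[i] for i in idx)
            key = tuple(t.text for t in normalize(word, self._cfg))
            if len(key) == 1 and key[0] not in self._used:
                self._used.add(key[0])
                return word
            logger.debug("coined word %r collides after normalization; retrying", word)
        raise RuntimeError("could not coin a fresh word after 1000 tries")


_EXCLUDED_ABBREVS = {
    "Injury, poisoning and procedural complications": "Inj&P",
    "Investigations": "Inv",
    "Social circumstances": "SocCi",
    "Surgical and medical procedures": "Surg",
    "Product issues": "Prod",
}

# special families planted under the failure-mode flags
_SPECIAL_RESERVED = (
    "Hepatitis A", "Hepatitis B", "Hepatitis D", "Myocardial infarction",
    "Dependence", "Addiction", "Suicidal behavior",
)


def generate_dictionary(
    spec: GeneratorSpec, out_dir: Optional[str] = None
) -> Dictionary:
    """Generate a MedDRA-style dictionary per the spec.

    Regular content: ``(n_socs + n_excluded_socs) * n_pts_per_soc`` PTs,
    each with its own name as an LLT plus ``n_llts_per_pt`` synonyms (the
    first synonym is a two-word term, used for reworded-mention planting).
    Failure-mode flags add the stop-word family (Hepatitis / A / B / D),
    the nested pair (Infarction / Myocardial infarction) and, with a
    reworded rate, the Dependence (LLT Addiction) and Suicidal behavior
    terms.  When ``out_dir`` is given, the '$'-delimited ASCII files are
    written there.
    """
    rng = np.random.default_rng([spec.seed, 0])
    forge = _WordForge(rng, extra_reserved=_SPECIAL_RESERVED)

    soc_code = _CODES["SOC"]
    pt_code = _CODES["PT"]
    llt_code = _CODES["LLT"]
    socs: Dict[int, TermRecord] = {}
    pts: Dict[int, TermRecord] = {}
    llts: Dict[int, TermRecord] = {}
    disorder_codes: List[int] = []

    fm = spec.failure_modes
    fixed_socs: List[Tuple[str, str]] = []
    if fm.stopword_terms:
        fixed_socs += [("Hepatobiliary disorders", "Hepat"),
                       ("Infections and infestations", "Infec")]
    if fm.nested_terms:
        fixed_socs += [("Cardiac disorders", "Card"),
                       ("Vascular disorders", "Vasc")]
    if fm.reworded_rate > 0:
        fixed_socs += [("Psychiatric disorders", "Psych")]

    for i in range(spec.n_socs):
        if i < len(fixed_socs):
            name, abbrev = fixed_socs[i]
        else:
            word = forge.coin().capitalize()
            name, abbrev = f"{word} disorders", word[:4].capitalize() + str(i)
        socs[soc_code] = TermRecord(
            code=soc_code, name=name, level="SOC", soc_abbrev=abbrev
        )
        disorder_codes.append(soc_code)
        soc_code += 1
    for i in range(spec.n_excluded_socs):
        name = DEFAULT_EXCLUDED_SOC_NAMES[i % len(DEFAULT_EXCLUDED_SOC_NAMES)]
        if i >= len(DEFAULT_EXCLUDED_SOC_NAMES):
            name = f"{name} ({i})"
        socs[soc_code] = TermRecord(
            code=soc_code, name=name, level="SOC",
            soc_abbrev=_EXCLUDED_ABBREVS.get(name, name[:4]),
        )
        soc_code += 1

    def add_pt(name: str, soc: int) -> int:
        nonlocal pt_code, llt_code
        rec = TermRecord(code=pt_code, name=name, level="PT", primary_soc_code=soc)
        pts[pt_code] = rec
        llts[llt_code] = TermRecord(
            code=llt_code, name=name, level="LLT", parent_pt_code=pt_code
        )
        llt_code += 1
        pt_code += 1
        return rec.code

    def add_llt(name: str, parent: int) -> None:
        nonlocal llt_code
        llts[llt_code] = TermRecord(
            code=llt_code, name=name, level="LLT", parent_pt_code=parent
        )
        llt_code += 1

    for soc in sorted(socs):
        for _ in range(spec.n_pts_per_soc):
            base = forge.coin().capitalize()
            p = add_pt(base, soc)
            # two-word synonym (reworded-mention substrate)
            add_llt(f"{forge.coin().capitalize()} {forge.coin()}", p)
            for _ in range(spec.n_llts_per_pt - 1):
                add_llt(forge.coin().capitalize(), p)

    special: Dict[str, int] = {}
    by_name = {r.name: c for c, r in socs.items()}
    if fm.stopword_terms:
        special["Hepatitis"] = add_pt("Hepatitis", by_name["Hepatobiliary disorders"])
        for suffix in ("A", "B", "D"):
            special[f"Hepatitis {suffix}"] = add_pt(
                f"Hepatitis {suffix}", by_name["Infections and infestations"]
            )
    if fm.nested_terms:
        special["Myocardial infarction"] = add_pt(
            "Myocardial infarction", by_name["Cardiac disorders"]
        )
        special["Infarction"] = add_pt("Infarction", by_name["Vascular disorders"])
    if fm.reworded_rate > 0:
        dep = add_pt("Dependence", by_name["Psychiatric disorders"])
        add_llt("Addiction", dep)
        special["Dependence"] = dep
        special["Suicidal behavior"] = add_pt(
            "Suicidal behavior", by_name["Psychiatric disorders"]
        )

    d = Dictionary(
        llts=llts, pts=pts, socs=socs,
        disorder_soc_codes=frozenset(disorder_codes),
    )
    d.validate()
    object.__setattr__(d, "special_pts", special)  # frozen dataclass; ad-hoc annotation
    if out_dir is not None:
        write_dictionary(d, out_dir)
    return d


# -- corpus ----------------------------------------------------------------

_SPL_TEMPLATE = """<?xml version="1.0" encoding="UTF-8"?>
<document xmlns="urn:hl7-org:v3">
  <id root="{doc_id}"/>
  <setId root="{set_id}"/>
  <effectiveTime value="{date}"/>
  <subject>
    <manufacturedProduct>
{ingredients}      <subjectOf>
        <approval>
          <code code="{app_code}" displayName="{app_name}"/>
        </approval>
      </subjectOf>
    </manufacturedProduct>
  </subject>
  <component>
    <structuredBody>
{sections}    </structuredBody>
  </component>
</document>
"""

_INGREDIENT = """      <ingredient classCode="ACTIB">
        <ingredientSubstance>
          <code code="{unii}" codeSystem="2.16.840.1.113883.4.9"/>
          <name>{name}</name>
        </ingredientSubstance>
      </ingredient>
"""

_SECTION = """      <component>
        <section>
          <code code="{loinc}" codeSystem="2.16.840.1.113883.6.1"/>
          <title>{title}</title>
          <text><paragraph>{text}</paragraph></text>
        </section>
      </component>
"""

_SECTION_TITLES = {
    "34066-1": "BOXED WARNING",
    "43685-7": "WARNINGS AND PRECAUTIONS",
    "34084-4": "ADVERSE REACTIONS",
}


def _spl_xml(doc: LabelDocument) -> str:
    ingredients = "".join(
        _INGREDIENT.format(unii=f"{doc.unii}" if i == 0 else f"{doc.unii}X{i}",
                           name=f"ingredient {i}")
        for i in range(doc.ingredient_count)
    )
    app = doc.application_type
    sections = "".join(
        _SECTION.format(loinc=code, title=sec.title, text=sec.text)
        for code, sec in doc.sections.items()
    )
    return _SPL_TEMPLATE.format(
        doc_id=f"ID-{doc.set_id}",
        set_id=doc.set_id,
        date=doc.effective_date.strftime("%Y%m%d"),
        ingredients=ingredients,
        app_code={"NDA": "C73594", "ANDA": "C73584", "BLA": "C73585",
                  "OTC": "C73603"}.get(app, "C00000"),
        app_name={"OTC": "OTC monograph final"}.get(app, app),
        sections=sections,
    )


def _filler(rng: np.random.Generator, lo: int, hi: int) -> List[str]:
    k = int(rng.integers(lo, hi + 1))
    idx = rng.integers(0, len(FILLER_WORDS), size=k)
    return [FILLER_WORDS[i] for i in idx]


def _surface(rng: np.random.Generator, name: str) -> str:
    """Case-jitter a planted surface form."""
    u = rng.random()
    if u < 0.15:
        return name.upper()
    if u < 0.45:
        return name.lower()
    return name


def generate_corpus(
    spec: GeneratorSpec,
    d: Dictionary,
    out_dir: Optional[str] = None,
) -> CorpusBundle:
    """Generate labeled documents with known planted PT mentions.

    Each drug is a single-ingredient NDA label.  ``round(n * fraction)``
    drugs (chosen at random) carry each section; a present section plants
    ``1 + Poisson(rate - 1)`` distinct PTs as verbatim LLT surface forms
    separated by filler prose.  Gold annotations list every planted PT per
    section, including reworded (unmatchable) mentions; those are listed
    separately in the ground truth.
    """
    rng = np.random.default_rng([spec.seed, 1])
    fm = spec.failure_modes

    disorder_pts = sorted(p for p in d.pts if d.is_disorder_pt(p))
    pt_arr = np.array(disorder_pts)

    # per-PT surface forms: [(llt_name, is_two_word), ...]
    surfaces: Dict[int, List[str]] = {p: [] for p in d.pts}
    for llt in sorted(d.llts.values(), key=lambda r: r.code):
        surfaces[llt.parent_pt_code].append(llt.name)
    two_word: Dict[int, Optional[str]] = {
        p: next((s for s in names if len(s.split()) == 2), None)
        for p, names in surfaces.items()
    }

    enriched_code: Optional[int] = None
    weights = np.ones(len(pt_arr), dtype=float)
    if spec.enriched_soc is not None:
        disorder_socs = sorted(d.disorder_soc_codes)
        enriched_code = disorder_socs[spec.enriched_soc % len(disorder_socs)]
        for j, p in enumerate(disorder_pts):
            if d.pt_primary_soc(p) == enriched_code:
                weights[j] = spec.enrichment_multiplier
    base_probs = weights / weights.sum()
    uniform_probs = np.ones(len(pt_arr)) / len(pt_arr)

    # ATC universe and assignment
    letters = "ABCDGHJLMNPRSV"
    atc_codes = [
        f"{letters[i % len(letters)]}{i // len(letters) + 1:02d}"
        for i in range(spec.n_atc_groups)
    ]
    block_of_atc: Dict[str, int] = {}
    block_pts: Dict[int, List[int]] = {}
    taken: Set[int] = set()
    for b, block in enumerate(spec.atc_blocks):
        for code in block.atc_codes:
            block_of_atc[code] = b
        pool = [p for p in disorder_pts if p not in taken]
        chosen = list(rng.choice(pool, size=block.n_shared_pts, replace=False))
        block_pts[b] = [int(p) for p in chosen]
        taken.update(block_pts[b])

    n = spec.n_drugs
    n_bw = round(n * spec.bw_fraction)
    n_wp = round(n * spec.wp_fraction)
    n_ar = round(n * spec.ar_fraction)
    has = {}
    for sec, count in (("BW", n_bw), ("WP", n_wp), ("AR", n_ar)):
        mask = np.zeros(n, dtype=bool)
        mask[rng.permutation(n)[:count]] = True
        has[sec] = mask

    documents: List[LabelDocument] = []
    xml_by_id: Dict[str, str] = {}
    gold: List[GoldAnnotation] = []
    atc_entries: Dict[str, Set[str]] = {}
    planted: Dict[str, Dict[str, Set[int]]] = {}
    unmatchable: List[Tuple[str, str, int]] = []

    base_date = _dt.date(2016, 1, 1)
    rates = dict(zip(("BW", "WP", "AR"), spec.section_rates))

    for i in range(n):
        set_id = f"SYN-{i:05d}"
        unii = f"U{i:06d}"
        codes = {atc_codes[int(rng.integers(0, len(atc_codes)))]}
        if spec.multi_atc_rate and rng.random() < spec.multi_atc_rate:
            codes.add(atc_codes[int(rng.integers(0, len(atc_codes)))])
        atc_entries[set_id] = codes

        in_blocks = sorted({block_of_atc[c] for c in codes if c in block_of_atc})
        if in_blocks:
            has["BW"][i] = True  # block structure is a Boxed-Warning pattern

        sections: Dict[str, LabelSection] = {}
        planted[set_id] = {}
        for sec in ("BW", "WP", "AR"):
            if not has[sec][i]:
                continue
            loinc = DEFAULT_LOINC_MAP[sec]
            k = 1 + int(rng.poisson(rates[sec] - 1.0))
            probs = base_probs if sec == "BW" else uniform_probs
            k = min(k, len(pt_arr))
            chosen = [int(p) for p in
                      rng.choice(pt_arr, size=k, replace=False, p=probs)]
            if sec == "BW":
                for b in in_blocks:
                    chosen.extend(p for p in block_pts[b] if p not in chosen)
            words: List[str] = _filler(rng, 3, 8)
            sec_planted: Set[int] = set()
            for p in chosen:
                sec_planted.add(p)
                names = surfaces[p]
                reworded = (
                    fm.reworded_rate > 0
                    and two_word[p] is not None
                    and rng.random() < fm.reworded_rate
                )
                if reworded:
                    w1, w2 = two_word[p].split()
                    gap = _filler(rng, 1, 2)
                    words.extend([w1, *gap, "and", w2])
                    unmatchable.append((set_id, loinc, p))
                else:
                    name = names[int(rng.integers(0, len(names)))]
                    words.append(_surface(rng, name))
                words.extend(_filler(rng, 2, 5))
                if rng.random() < 0.3:
                    words[-1] += "."
            planted[set_id][loinc] = sec_planted
            gold.append(GoldAnnotation(
                set_id=set_id, section_loinc=loinc,
                pt_codes=frozenset(sec_planted),
            ))
            sections[loinc] = LabelSection(
                loinc_code=loinc,
                title=_SECTION_TITLES.get(loinc, sec),
                text=" ".join(words),
            )

        doc = LabelDocument(
            set_id=set_id,
            unii=unii,
            ingredient_count=1,
            application_type="NDA",
            effective_date=base_date + _dt.timedelta(days=int(rng.integers(0, 500))),
            sections=sections,
        )
        documents.append(doc)
        xml_by_id[set_id] = _spl_xml(doc)

    gt = GroundTruth(
        planted=planted,
        unmatchable=unmatchable,
        enriched_soc_code=enriched_code,
        atc_partition=dict(sorted(block_of_atc.items())),
        special_pts=dict(getattr(d, "special_pts", {})),
    )
    bundle = CorpusBundle(
        documents=documents,
        xml_by_set_id=xml_by_id,
        gold=gold,
        atc=ATCMap(entries=atc_entries),
        ground_truth=gt,
    )
    if out_dir is not None:
        write_bundle(bundle, out_dir)
    return bundle


def write_bundle(bundle: CorpusBundle, out_dir: str) -> None:
    """Write SPL XML files, gold TSV, ATC TSV and ground-truth JSON."""
    spl_dir = os.path.join(out_dir, "spl")
    os.makedirs(spl_dir, exist_ok=True)
    for set_id in sorted(bundle.xml_by_set_id):
        with open(os.path.join(spl_dir, f"{set_id}.xml"), "w",
                  encoding="utf-8") as fh:
            fh.write(bundle.xml_by_set_id[set_id])
    with open(os.path.join(out_dir, "gold.tsv"), "w", encoding="utf-8") as fh:
        for g in sorted(bundle.gold, key=lambda g: (g.set_id, g.section_loinc)):
            for pt in sorted(g.pt_codes):
                fh.write(f"{g.set_id}\t{g.section_loinc}\t{pt}\n")
    write_atc_tsv(bundle.atc, os.path.join(out_dir, "atc.tsv"))
    gt = bundle.ground_truth
    with open(os.path.join(out_dir, "ground_truth.json"), "w",
              encoding="utf-8") as fh:
        json.dump({
            "planted": {
                sid: {sec: sorted(pts) for sec, pts in sorted(secs.items())}
                for sid, secs in sorted(gt.planted.items())
            },
            "unmatchable": sorted(gt.unmatchable),
            "enriched_soc_code": gt.enriched_soc_code,
            "atc_partition": gt.atc_partition,
            "special_pts": gt.special_pts,
        }, fh, indent=1, sort_keys=True)


def selection_fixture() -> Tuple[List[LabelDocument], List[str]]:
    """Ten hand-built documents exercising all four selection criteria.

    Composition: 2 OTC labels (criterion I), 2 ANDA labels (criterion II),
    1 two-ingredient label (criterion III), one duplicate-UNII pair with
    distinct dates (criterion IV) and 3 unique single-ingredient NDA
    labels.  Hand-applying the criteria leaves exactly the returned
    survivor set_ids (4 of them): the later document of the duplicate pair
    plus the three unique NDA labels.
    """
    def doc(set_id, unii, app, n_ing, date):
        return LabelDocument(
            set_id=set_id, unii=unii, ingredient_count=n_ing,
            application_type=app, effective_date=date,
            sections={
                "34084-4": LabelSection("34084-4", "ADVERSE REACTIONS",
                                        "lorem ipsum dolor"),
            },
        )

    docs = [
        doc("FIX-01", "U-OTC1", "OTC", 1, _dt.date(2016, 5, 1)),
        doc("FIX-02", "U-OTC2", "OTC", 1, _dt.date(2016, 6, 1)),
        doc("FIX-03", "U-AND1", "ANDA", 1, _dt.date(2016, 7, 1)),
        doc("FIX-04", "U-AND2", "ANDA", 1, _dt.date(2016, 8, 1)),
        doc("FIX-05", "U-MULT", "NDA", 2, _dt.date(2016, 9, 1)),
        doc("FIX-06", "U-DUP1", "NDA", 1, _dt.date(2016, 1, 1)),
        doc("FIX-07", "U-DUP1", "NDA", 1, _dt.date(2017, 3, 20)),
        doc("FIX-08", "U-NDA1", "NDA", 1, _dt.date(2016, 2, 2)),
        doc("FIX-09", "U-NDA2", "NDA", 1, _dt.date(2016, 3, 3)),
        doc("FIX-10", "U-NDA3", "NDA", 1, _dt.date(2016, 4, 4)),
    ]
    survivors = ["FIX-07", "FIX-08", "FIX-09", "FIX-10"]
    return docs, survivors


# -- matrix-level calibration samplers ------------------------------------

def sample_bw_universe(
    d: Dictionary,
    rng: np.random.Generator,
    bw_rate: float = 0.45,
    enriched_soc_code: Optional[int] = None,
    multiplier: float = 1.0,
) -> DrugPTMatrix:
    """Sample PT-level Boxed-Warning membership over the disorder universe.

    Each disorder PT enters the BW set independently with probability
    ``bw_rate`` (times ``multiplier``, capped at 1, for PTs of the
    enriched SOC).  Returns a minimal one-pseudo-drug occurrence matrix
    whose whole-document slice is the full universe — exactly the
    sufficient statistics of the per-SOC enrichment test.  Used for
    statistical calibration (null size, planted-effect power) without the
    cost of text generation.
    """
    pts = sorted(p for p in d.pts if d.is_disorder_pt(p))
    probs = np.full(len(pts), bw_rate)
    if enriched_soc_code is not None:
        for j, p in enumerate(pts):
            if d.pt_primary_soc(p) == enriched_soc_code:
                probs[j] = min(1.0, bw_rate * multiplier)
    bw_mask = rng.random(len(pts)) < probs

    occ = np.zeros((1, len(pts), len(SECTIONS)), dtype=np.uint8)
    occ[0, :, SECTIONS.index("whole")] = 1
    occ[0, :, SECTIONS.index("BW")] = bw_mask
    presence = np.array([[True, False, False]])
    return DrugPTMatrix(
        set_ids=["PSEUDO-0"],
        pt_codes=pts,
        occurrence=occ,
        section_presence=presence,
        pt_names={p: d.pt_name(p) for p in pts},
    )


def sample_block_matrix(
    rng: np.random.Generator,
    n_blocks: int = 2,
    atcs_per_block: int = 4,
    drugs_per_atc: int = 6,
    pts_per_block: int = 8,
) -> Tuple[DrugPTMatrix, ATCMap, Dict[str, int]]:
    """Planted-block drug x PT matrix for cluster-recovery checks.

    Blocks have disjoint Boxed-Warning PT profiles; every drug belongs to
    one ATC class and every class to one block.  Returns the matrix, the
    ATC map, and the planted class -> block partition.
    """
    letters = "LNJACDM"  # one letter per block, numbered classes
    atc_codes = [
        f"{letters[b % len(letters)]}{a + 1:02d}"
        for b in range(n_blocks) for a in range(atcs_per_block)
    ]
    partition = {
        code: b
        for b in range(n_blocks) for code in
        atc_codes[b * atcs_per_block:(b + 1) * atcs_per_block]
    }
    pt_codes = list(range(50_000_001, 50_000_001 + n_blocks * pts_per_block))
    block_pt = {
        b: pt_codes[b * pts_per_block:(b + 1) * pts_per_block]
        for b in range(n_blocks)
    }

    set_ids, entries = [], {}
    rows = []
    for code in atc_codes:
        b = partition[code]
        for k in range(drugs_per_atc):
            sid = f"BLK-{code}-{k:02d}"
            set_ids.append(sid)
            entries[sid] = {code}
            # every drug mentions most of its block's PTs (one random gap
            # keeps profiles non-identical without breaking separation)
            mine = set(block_pt[b])
            if len(mine) > 1:
                mine.discard(block_pt[b][int(rng.integers(0, pts_per_block))])
            rows.append(mine)

    occ = np.zeros((len(set_ids), len(pt_codes), len(SECTIONS)), dtype=np.uint8)
    pt_ix = {p: j for j, p in enumerate(pt_codes)}
    for i, mine in enumerate(rows):
        for p in mine:
            occ[i, pt_ix[p], SECTIONS.index("BW")] = 1
            occ[i, pt_ix[p], SECTIONS.index("whole")] = 1
    presence = np.zeros((len(set_ids), 3), dtype=bool)
    presence[:, 0] = True
    m = DrugPTMatrix(
        set_ids=set_ids,
        pt_codes=pt_codes,
        occurrence=occ,
        section_presence=presence,
        pt_names={p: f"PT{p}" for p in pt_codes},
    )
    return m, ATCMap(entries=entries), partition
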