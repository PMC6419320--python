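"""Shared fixtures: a tiny hand-built dictionary and generated corpora."""

from __future__ import annotations

import datetime as dt

import pytest

import labelsafe as ls
from labelsafe.synth import FailureModes

# -- tiny hand-built terminology: 3 SOCs, 4 PTs, 9 LLTs --------------------

TINY_SOC_LINES = [
    "10000001$Psychiatric disorders$Psych$",
    "10000002$Hepatobiliary disorders$Hepat$",
    "10000003$Cardiac disorders$Card$",
]
TINY_PT_LINES = [
    "20000001$Dependence$$10000001$",
    "20000002$Hepatitis$$10000002$",
    "20000003$Myocardial infarction$$10000003$",
    "20000004$Pyrexia$$10000001$",
]
TINY_LLT_LINES = [
    "30000001$Dependence$20000001$",
    "30000002$Addiction$20000001$",
    "30000003$Drug dependence$20000001$",
    "30000004$Hepatitis$20000002$",
    "30000005$Hepatitis viral$20000002$",
    "30000006$Myocardial infarction$20000003$",
    "30000007$Heart attack$20000003$",
    "30000008$Pyrexia$20000004$",
    "30000009$Fever$20000004$",
]


def write_tiny_dictionary(dirpath, soc=None, pt=None, llt=None):
    """Write the tiny fixture (optionally with overridden lines)."""
    paths = {}
    for name, lines in (
        ("soc", soc or TINY_SOC_LINES),
        ("pt", pt or TINY_PT_LINES),
        ("llt", llt or TINY_LLT_LINES),
    ):
        p = dirpath / f"{name}.asc"
        p.write_text("\n".join(lines) + "\n", encoding="ascii")
        paths[name] = str(p)
    return paths


@pytest.fixture
def tiny_dict_paths(tmp_path):
    return write_tiny_dictionary(tmp_path)


@pytest.fixture
def tiny_dict(tiny_dict_paths):
    return ls.load_dictionary(
        tiny_dict_paths["llt"], tiny_dict_paths["pt"], tiny_dict_paths["soc"]
    )


# -- generated dictionaries / corpora (session-scoped for speed) -----------

@pytest.fixture(scope="session")
def fm_spec():
    """Small study spec with every matcher failure mode enabled."""
    return ls.GeneratorSpec(
        seed=11, n_socs=8, n_excluded_socs=2, n_pts_per_soc=3, n_drugs=40,
        failure_modes=FailureModes(
            stopword_terms=True, nested_terms=True, reworded_rate=0.1
        ),
    )


@pytest.fixture(scope="session")
def fm_dict(fm_spec):
    return ls.generate_dictionary(fm_spec)


@pytest.fixture(scope="session")
def clean_spec():
    """Small study spec with failure modes disabled (exact known answers)."""
    return ls.GeneratorSpec(
        seed=7, n_socs=6, n_excluded_socs=2, n_pts_per_soc=4, n_drugs=80
    )


@pytest.fixture(scope="session")
def clean_dict(clean_spec):
    return ls.generate_dictionary(clean_spec)


@pytest.fixture(scope="session")
def clean_bundle(clean_spec, clean_dict):
    return ls.generate_corpus(clean_spec, clean_dict)


@pytest.fixture(scope="session")
def clean_extraction(clean_dict, clean_bundle):
    cfg = ls.MatchConfig()
    index = ls.build_index(clean_dict, cfg)
    corpus = ls.Corpus(documents=clean_bundle.documents, selection_log={})
    results = [
        ls.extract_terms(doc, index, clean_dict, cfg) for doc in corpus.documents
    ]
    return corpus, results


def make_doc(text, loinc="34066-1", set_id="DOC-1", **kwargs):
    """One-section LabelDocument for matcher tests."""
    sections = {
        loinc: ls.LabelSection(loinc_code=loinc, title="", text=text)
    }
    defaults = dict(
        set_id=set_id, unii="U1", ingredient_count=1,
        application_type="NDA", effective_date=dt.date(2017, 1, 1),
    )
    defaults.update(kwargs)
    return ls.LabelDocument(sections=sections, **defaults)
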