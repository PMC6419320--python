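"""Normalization, term indexing, and the two match policies."""

import pytest
from hypothesis import given, settings, strategies as st

import labelsafe as ls
from labelsafe.matcher import MatcherConfigError, Token, porter_stem
from labelsafe.meddra import Dictionary, TermRecord

from conftest import make_doc


CFG = ls.MatchConfig()
CFG_LONGEST = ls.MatchConfig(match_policy="longest_match")


def toks(text, cfg=CFG):
    return [t.text for t in ls.normalize(text, cfg)]


class TestNormalize:
    def test_stop_word_bearing_term_equals_bare_term(self):
        assert toks("Hepatitis A") == toks("Hepatitis")
        assert toks("Hepatitis D") == toks("Hepatitis")

    def test_empty_text_yields_empty_sequence(self):
        assert ls.normalize("", CFG) == []

    def test_interposed_token_breaks_contiguity(self):
        reworded = toks("Suicidal thinking and behavior")
        term = toks("suicidal behavior")
        assert len(term) == 2
        # the dictionary bigram is not a contiguous subsequence
        assert all(
            reworded[i:i + 2] != term for i in range(len(reworded) - 1)
        )

    def test_spans_slice_raw_text(self):
        raw = "Severe  Drug-induced   hepatitis!"
        for t in ls.normalize(raw, CFG):
            assert 0 <= t.begin < t.end <= len(raw)
            assert raw[t.begin:t.end].isalnum()

    def test_hyphen_and_slash_split_tokens(self):
        assert len(ls.normalize("drug-induced/toxic", CFG)) == 3

    def test_stemming_can_be_disabled(self):
        cfg = ls.MatchConfig(stemming=False)
        assert toks("hepatitis", cfg) == ["hepatitis"]

    def test_uppercase_stop_words_rejected(self):
        with pytest.raises(MatcherConfigError):
            ls.MatchConfig(stop_words=frozenset({"The"}))


class TestPorterStem:
    @pytest.mark.parametrize("word,stem", [
        ("hepatitis", "hepat"),
        ("infarction", "infarct"),
        ("caresses", "caress"),
        ("ponies", "poni"),
        ("running", "run"),
        ("relational", "relat"),
        ("sensibility", "sensibl"),
    ])
    def test_classic_examples(self, word, stem):
        assert porter_stem(word) == stem


def _mini_dict(names_by_pt):
    """Dictionary with one SOC; names_by_pt: {pt_name: [llt_names]}."""
    socs = {1: TermRecord(code=1, name="Test disorders", level="SOC",
                          soc_abbrev="Test")}
    pts, llts = {}, {}
    pt_code, llt_code = 100, 1000
    for pt_name, llt_names in names_by_pt.items():
        pts[pt_code] = TermRecord(code=pt_code, name=pt_name, level="PT",
                                  primary_soc_code=1)
        for n in [pt_name] + list(llt_names):
            llts[llt_code] = TermRecord(code=llt_code, name=n, level="LLT",
                                        parent_pt_code=pt_code)
            llt_code += 1
        pt_code += 1
    d = Dictionary(llts=llts, pts=pts, socs=socs,
                   disorder_soc_codes=frozenset({1}))
    d.validate()
    return d


HEP_DICT = _mini_dict({
    "Hepatitis": [], "Hepatitis A": [], "Hepatitis D": [], "Hepatitis B": [],
    "Myocardial infarction": [], "Infarction": [],
    "Suicidal behavior": [],
    "Fall": [],
})


class TestBuildIndex:
    def test_stop_word_family_collides_to_one_entry(self):
        index = ls.build_index(HEP_DICT, CFG)
        groups = index.collision_groups()
        assert len(groups) == 1
        (codes,) = groups.values()
        names = {HEP_DICT.llts[c].name for c in codes}
        assert names == {"Hepatitis", "Hepatitis A", "Hepatitis D"}

    def test_disjoint_names_give_one_entry_per_llt(self, clean_dict):
        index = ls.build_index(clean_dict, CFG)
        assert len(index.entries) == len(clean_dict.llts)
        assert not index.collision_groups()

    def test_llt_normalizing_to_empty_excluded_with_warning(self, caplog):
        d = _mini_dict({"Pain": [], "A": []})
        with caplog.at_level("WARNING"):
            index = ls.build_index(d, CFG)
        assert all(key for key in index.entries)
        assert any("empty" in r.message for r in caplog.records)

    def test_multiple_meaning_single_token_term_indexed(self):
        index = ls.build_index(HEP_DICT, CFG)
        assert (porter_stem("fall"),) in index.entries


def pts_of(doc, d, cfg, section="34066-1"):
    index = ls.build_index(d, cfg)
    res = ls.extract_terms(doc, index, d, cfg, section_codes=[section])
    return {d.pt_name(p) for p in res.per_section_pts[section]}


class TestExtractTerms:
    def test_nested_term_policies_differ(self):
        doc = make_doc("increased risk of myocardial infarction events")
        assert pts_of(doc, HEP_DICT, CFG) == {"Myocardial infarction", "Infarction"}
        assert pts_of(doc, HEP_DICT, CFG_LONGEST) == {"Myocardial infarction"}

    def test_hepatitis_b_triggers_collision_group(self):
        doc = make_doc("monitor for Hepatitis B reactivation")
        assert pts_of(doc, HEP_DICT, CFG) == {
            "Hepatitis", "Hepatitis A", "Hepatitis D", "Hepatitis B"
        }

    def test_reworded_mention_not_matched(self):
        doc = make_doc("suicidal thinking and behavior were reported")
        assert pts_of(doc, HEP_DICT, CFG) == set()
        assert pts_of(doc, HEP_DICT, CFG_LONGEST) == set()

    def test_repeated_mentions_count_once_per_section(self):
        doc = make_doc(" ".join(["infarction occurred."] * 5))
        index = ls.build_index(HEP_DICT, CFG)
        res = ls.extract_terms(doc, index, HEP_DICT, CFG,
                               section_codes=["34066-1"])
        assert len(res.per_section_pts["34066-1"]) == 1
        assert len([m for m in res.matches]) == 5  # provenance keeps all

    def test_excluded_soc_pts_dropped(self):
        socs = {
            1: TermRecord(code=1, name="Cardiac disorders", level="SOC",
                          soc_abbrev="Card"),
            2: TermRecord(code=2, name="Investigations", level="SOC",
                          soc_abbrev="Inv"),
        }
        pts = {
            10: TermRecord(code=10, name="Infarction", level="PT",
                           primary_soc_code=1),
            11: TermRecord(code=11, name="Troponin increased", level="PT",
                           primary_soc_code=2),
        }
        llts = {
            100: TermRecord(code=100, name="Infarction", level="LLT",
                            parent_pt_code=10),
            101: TermRecord(code=101, name="Troponin increased", level="LLT",
                            parent_pt_code=11),
        }
        d = Dictionary(llts=llts, pts=pts, socs=socs,
                       disorder_soc_codes=frozenset({1}))
        doc = make_doc("infarction with troponin increased")
        assert pts_of(doc, d, CFG) == {"Infarction"}

    def test_unknown_section_code_raises(self):
        doc = make_doc("text")
        index = ls.build_index(HEP_DICT, CFG)
        with pytest.raises(MatcherConfigError):
            ls.extract_terms(doc, index, HEP_DICT, CFG,
                             section_codes=["not-a-section"])


class TestExtractionProperties:
    def test_appending_text_never_removes_pts(self):
        base = "risk of hepatitis b"
        doc1 = make_doc(base)
        doc2 = make_doc(base + " and myocardial infarction")
        assert pts_of(doc1, HEP_DICT, CFG) <= pts_of(doc2, HEP_DICT, CFG)

    def test_duplicated_section_is_idempotent(self):
        s = "hepatitis and myocardial infarction"
        assert pts_of(make_doc(s), HEP_DICT, CFG) == pts_of(
            make_doc(s + " " + s), HEP_DICT, CFG
        )

    def test_section_pts_subset_of_whole(self, clean_dict, clean_extraction):
        _, results = clean_extraction
        for res in results:
            whole = res.per_section_pts["whole"]
            for code, pts in res.per_section_pts.items():
                assert pts <= whole

    def test_longest_subset_of_all_matches(self):
        doc = make_doc("myocardial infarction and hepatitis b and falls")
        assert pts_of(doc, HEP_DICT, CFG_LONGEST) <= pts_of(doc, HEP_DICT, CFG)

    def test_planted_mentions_recovered_exactly(self, clean_dict, clean_bundle,
                                                clean_extraction):
        _, results = clean_extraction
        planted = clean_bundle.ground_truth.planted
        for res in results:
            for loinc, pts in planted[res.set_id].items():
                assert res.per_section_pts[loinc] == pts


# -- brute-force oracle ----------------------------------------------------

VOCAB = ["alpha", "beta", "gamma", "delta", "omega", "zeta", "a", "the",
         "hepatitis", "infarction", "myocardial", "pain", "falls"]


def brute_force_llts(text, d, cfg):
    """Test every (start, length) token window against every LLT."""
    tokens = toks(text, cfg)
    hits = set()
    for llt in d.llts.values():
        key = tuple(toks(llt.name, cfg))
        if not key:
            continue
        for i in range(len(tokens) - len(key) + 1):
            if tuple(tokens[i:i + len(key)]) == key:
                hits.add(llt.code)
                break
    return hits


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_all_matches_equals_brute_force_window_scan(data):
    n_terms = data.draw(st.integers(1, 12))
    term_names = data.draw(st.lists(
        st.lists(st.sampled_from(VOCAB), min_size=1, max_size=3).map(" ".join),
        min_size=n_terms, max_size=n_terms, unique=True,
    ))
    d = _mini_dict({f"T{i}": [name] for i, name in enumerate(term_names)})
    text = " ".join(data.draw(st.lists(st.sampled_from(VOCAB), max_size=60)))
    doc = make_doc(text)
    index = ls.build_index(d, CFG)
    res = ls.extract_terms(doc, index, d, CFG, section_codes=["34066-1"])
    got = {m.llt_code for m in res.matches}
    assert got == brute_force_llts(text, d, CFG)
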