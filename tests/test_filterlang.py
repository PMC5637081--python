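"""Ovid filter parsing, serialisation and Boolean evaluation semantics."""

from __future__ import annotations

import pytest
from hypothesis import given
from hypothesis import strategies as st

import hedgekit as hk
from conftest import naive_evaluate, naive_retrieve


class TestParse:
    def test_two_term_or(self):
        expr = hk.parse_filter("paramedic*.tw OR ems.tw")
        assert expr == hk.Or(
            hk.FilterTerm("paramedic", "tw", truncated=True),
            hk.FilterTerm("ems", "tw"),
        )

    def test_atom_text_case_folded_and_multiword(self):
        term = hk.parse_term("Emergency Medical Technicians.sh")
        assert term == hk.FilterTerm("emergency medical technicians", "sh")

    def test_precedence_not_and_or(self):
        expr = hk.parse_filter("a.tw OR NOT b.tw AND c.tw")
        assert expr == hk.Or(
            hk.FilterTerm("a", "tw"),
            hk.And(hk.Not(hk.FilterTerm("b", "tw")), hk.FilterTerm("c", "tw")),
        )

    def test_parentheses_override_precedence(self):
        expr = hk.parse_filter("(a.tw OR b.tw) AND c.tw")
        assert expr == hk.And(
            hk.Or(hk.FilterTerm("a", "tw"), hk.FilterTerm("b", "tw")),
            hk.FilterTerm("c", "tw"),
        )

    def test_or_chain_flattens_to_nary_node(self):
        expr = hk.parse_filter("a.tw OR b.tw OR c.tw")
        assert isinstance(expr, hk.Or) and len(expr.children) == 3

    @pytest.mark.parametrize(
        "bad",
        [
            "",
            "   ",
            "paramedic.xx",  # unknown field tag
            "a.tw OR",  # dangling operator
            "(a.tw OR b.tw",  # unbalanced parentheses
            "para*medic.tw",  # mid-word wildcard
            "*.tw",  # no term text
            "OR a.tw",
        ],
    )
    def test_parse_errors(self, bad):
        with pytest.raises(hk.FilterParseError):
            hk.parse_filter(bad)

    def test_error_carries_position(self):
        with pytest.raises(hk.FilterParseError, match="position"):
            hk.parse_filter("ems.tw OR paramedic.xx")


class TestSerialize:
    def test_canonical_or(self):
        expr = hk.Or(hk.FilterTerm("ems", "tw"), hk.FilterTerm("emt", "tw"))
        assert hk.serialize_filter(expr) == "ems.tw OR emt.tw"

    def test_single_truncated_leaf(self):
        assert (
            hk.serialize_filter(hk.FilterTerm("paramedic", "tw", truncated=True))
            == "paramedic*.tw"
        )

    def test_parentheses_only_where_precedence_requires(self):
        expr = hk.And(
            hk.Or(hk.FilterTerm("a", "tw"), hk.FilterTerm("b", "tw")),
            hk.FilterTerm("c", "tw"),
        )
        assert hk.serialize_filter(expr) == "(a.tw OR b.tw) AND c.tw"
        expr2 = hk.Or(
            hk.And(hk.FilterTerm("a", "tw"), hk.FilterTerm("b", "tw")),
            hk.FilterTerm("c", "tw"),
        )
        assert hk.serialize_filter(expr2) == "a.tw AND b.tw OR c.tw"


class TestMatchTerm:
    def test_truncation_prefix_match(self, six_records):
        term = hk.FilterTerm("paramedic", "tw", truncated=True)
        assert hk.match_term(term, six_records["1"])  # token "paramedics"

    def test_whole_token_rule_blocks_substrings(self, six_records):
        # "Emsworth" must not match the untruncated token "ems"
        assert not hk.match_term(hk.FilterTerm("ems", "tw"), six_records["2"])
        assert hk.match_term(hk.FilterTerm("ems", "tw"), six_records["1"])

    def test_subject_heading_qualifier_stripped(self, six_records):
        term = hk.FilterTerm("emergency medical technicians", "sh")
        assert hk.match_term(term, six_records["1"])

    def test_sh_requires_whole_heading_equality(self, six_records):
        # record 3 carries "Emergency Medical Services", not "Emergency"
        assert not hk.match_term(hk.FilterTerm("emergency", "sh"), six_records["3"])
        assert hk.match_term(
            hk.FilterTerm("emergency medical services", "sh"), six_records["3"]
        )

    def test_hyphen_splitting_separates_spellings(self, six_records):
        prehosp = hk.FilterTerm("prehospital", "tw")
        pre_hosp = hk.parse_term("pre-hospital.tw")
        assert hk.match_term(prehosp, six_records["3"])
        assert not hk.match_term(pre_hosp, six_records["3"])
        assert hk.match_term(pre_hosp, six_records["4"])
        assert not hk.match_term(prehosp, six_records["4"])

    def test_tw_never_scans_mesh(self, six_records):
        # record 6's abstract mentions HEMS only via its words, mesh holds the heading
        assert not hk.match_term(hk.FilterTerm("air ambulances", "tw"), six_records["6"])
        assert hk.match_term(hk.FilterTerm("air ambulances", "sh"), six_records["6"])


class TestEvaluateRetrieve:
    def test_or_short_circuit_semantics(self, six_records):
        matching = hk.FilterTerm("paramedic", "tw", truncated=True)
        absent = hk.FilterTerm("zebra", "tw")
        assert hk.evaluate_filter(hk.Or(matching, absent), six_records["1"])
        assert not hk.evaluate_filter(hk.Not(matching), six_records["1"])

    def test_retrieve_on_empty_corpus(self):
        assert hk.retrieve(hk.FilterTerm("ems", "tw"), hk.Corpus()) == set()

    def test_or_retrieval_is_union(self, six_records):
        a = hk.FilterTerm("prehospital", "tw")
        b = hk.parse_term("pre-hospital.tw")
        assert hk.retrieve(hk.Or(a, b), six_records) == hk.retrieve(
            a, six_records
        ) | hk.retrieve(b, six_records)

    def test_retrieve_matches_brute_force_on_fixture(self, six_records):
        expr = hk.get_filter("paramedic_sensitivity").parse()
        assert hk.retrieve(expr, six_records) == naive_retrieve(expr, six_records)


# --- property-based checks --------------------------------------------------

token = st.text(alphabet="abc", min_size=1, max_size=3)
term_text = st.lists(token, min_size=1, max_size=2).map(" ".join)
terms = st.builds(
    hk.FilterTerm,
    text=term_text,
    field=st.sampled_from(["tw", "sh"]),
    truncated=st.booleans(),
)

exprs = st.recursive(
    terms,
    lambda children: st.one_of(
        st.lists(children, min_size=2, max_size=3).map(lambda c: hk.Or(*c)),
        st.lists(children, min_size=2, max_size=3).map(lambda c: hk.And(*c)),
        children.map(hk.Not),
    ),
    max_leaves=6,
)

records = st.builds(
    hk.BibRecord,
    record_id=st.uuids().map(str),
    title=st.lists(token, min_size=1, max_size=6).map(" ".join),
    abstract=st.lists(token, min_size=0, max_size=10).map(" ".join),
    mesh_headings=st.lists(term_text, max_size=3),
)

corpora = st.lists(records, min_size=1, max_size=8).map(hk.Corpus)


@given(expr=exprs)
def test_serialize_parse_round_trip(expr):
    """parse(serialize(e)) is structurally identical to e."""
    assert hk.parse_filter(hk.serialize_filter(expr)) == expr


@given(expr=exprs, record=records)
def test_evaluate_agrees_with_naive_reimplementation(expr, record):
    assert hk.evaluate_filter(expr, record) == naive_evaluate(expr, record)


@given(expr=exprs, term=terms, corpus=corpora)
def test_or_monotonicity_of_retrieval(expr, term, corpus):
    """Adding an OR-term never shrinks the retrieval set."""
    base = hk.retrieve(expr, corpus)
    widened = hk.retrieve(hk.Or(expr, term), corpus)
    assert widened >= base


@given(a=exprs, b=exprs, corpus=corpora)
def test_de_morgan_identity_over_retrieval(a, b, corpus):
    lhs = hk.retrieve(hk.Not(hk.Or(a, b)), corpus)
    rhs = hk.retrieve(hk.And(hk.Not(a), hk.Not(b)), corpus)
    assert lhs == rhs


@given(a=exprs, corpus=corpora)
def test_idempotence_over_retrieval(a, corpus):
    assert hk.retrieve(hk.Or(a, a), corpus) == hk.retrieve(a, corpus)
    assert hk.retrieve(hk.And(a, a), corpus) == hk.retrieve(a, corpus)
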