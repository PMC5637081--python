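"""Shared fixtures and independent oracles for the test suite.

The naive matcher below is a deliberately separate re-implementation of the
term-matching semantics (character-walk tokeniser, nested-loop phrase scan,
no regex) used as a brute-force oracle against the package's evaluator.
"""

from __future__ import annotations

import pytest
from hypothesis import HealthCheck, settings

import hedgekit as hk

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


# --- independent oracle -----------------------------------------------------


def naive_tokens(text: str) -> list[str]:
    """Character-walk tokeniser: lowercase, alphanumeric runs only."""
    out, cur = [], ""
    for ch in text.lower():
        if ("a" <= ch <= "z") or ("0" <= ch <= "9"):
            cur += ch
        elif cur:
            out.append(cur)
            cur = ""
    if cur:
        out.append(cur)
    return out


def naive_phrase_match(phrase: list[str], doc: list[str], truncated: bool) -> bool:
    for start in range(len(doc) - len(phrase) + 1):
        ok = True
        for offset, want in enumerate(phrase):
            got = doc[start + offset]
            last = offset == len(phrase) - 1
            if truncated and last:
                if got[: len(want)] != want:
                    ok = False
                    break
            elif got != want:
                ok = False
                break
        if ok:
            return True
    return False


def naive_match_term(term: hk.FilterTerm, record: hk.BibRecord) -> bool:
    phrase = naive_tokens(term.text)
    if term.field == "tw":
        return naive_phrase_match(
            phrase, naive_tokens(record.title), term.truncated
        ) or naive_phrase_match(phrase, naive_tokens(record.abstract), term.truncated)
    for heading in record.mesh_headings:
        bare = heading.split("/")[0]
        doc = naive_tokens(bare)
        if len(doc) == len(phrase) and naive_phrase_match(phrase, doc, term.truncated):
            return True
    return False


def naive_evaluate(expr: hk.FilterExpr, record: hk.BibRecord) -> bool:
    if isinstance(expr, hk.FilterTerm):
        return naive_match_term(expr, record)
    if isinstance(expr, hk.Or):
        return any(naive_evaluate(c, record) for c in expr.children)
    if isinstance(expr, hk.And):
        return all(naive_evaluate(c, record) for c in expr.children)
    if isinstance(expr, hk.Not):
        return not naive_evaluate(expr.child, record)
    raise TypeError(expr)


def naive_retrieve(expr: hk.FilterExpr, corpus: hk.Corpus) -> set[str]:
    return {r.record_id for r in corpus if naive_evaluate(expr, r)}


# --- fixtures ---------------------------------------------------------------


@pytest.fixture
def six_records() -> hk.Corpus:
    """Six handcrafted records spanning the matching edge cases."""
    return hk.Corpus(
        [
            hk.BibRecord(
                "1",
                title="Paramedics respond faster",
                abstract="A study of EMS analgesia in the field.",
                mesh_headings=["Emergency Medical Technicians/education"],
            ),
            hk.BibRecord(
                "2",
                title="Coastal towns of Emsworth",
                abstract="Local history of Emsworth harbour.",
                mesh_headings=["History, Modern"],
            ),
            hk.BibRecord(
                "3",
                title="Prehospital care systems",
                abstract="Review of prehospital care pathways.",
                mesh_headings=["Emergency Medical Services"],
            ),
            hk.BibRecord(
                "4",
                title="Pre-hospital thoracostomy",
                abstract="Pre-hospital interventions after trauma.",
                mesh_headings=["Ambulances"],
            ),
            hk.BibRecord(
                "5",
                title="Cardiology outcomes",
                abstract="Hospital cohort of cardiac patients.",
                mesh_headings=["Heart Diseases"],
            ),
            hk.BibRecord(
                "6",
                title="Air ambulance dispatch",
                abstract="Helicopter emergency medical services audit.",
                mesh_headings=["Air Ambulances/statistics"],
            ),
        ]
    )


@pytest.fixture
def six_gold() -> hk.GoldStandard:
    return hk.GoldStandard(
        {
            "1": hk.RELEVANT,
            "2": hk.IRRELEVANT,
            "3": hk.RELEVANT,
            "4": hk.RELEVANT,
            "5": hk.IRRELEVANT,
            "6": hk.RELEVANT,
        }
    )


@pytest.fixture(scope="session")
def study_sized_run() -> tuple[hk.Corpus, hk.GoldStandard]:
    """One study-sized synthetic reference set (2102 records), shared across
    tests to keep the suite fast."""
    return hk.generate_corpus(hk.default_corpus_spec(seed=42))


@pytest.fixture(scope="session")
def default_pool() -> list[hk.FilterTerm]:
    return [p.term for p in hk.default_term_profiles()]
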