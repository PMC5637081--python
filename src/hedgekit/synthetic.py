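"""Labelled MEDLINE-like corpus generator with known term-occurrence structure.

Real hedge validation needs a hand-screened reference set; none is publicly
deposited for the paramedic filters, so every pipeline stage here is
exercised on generated corpora whose statistical structure is known exactly.
Each record is filled with neutral vocabulary and each profiled term is
inserted independently with a class-conditional probability: ``p_relevant``
in relevant records, ``p_irrelevant`` in irrelevant ones.  Under that model a
single-term filter has expected sensitivity ``p_relevant`` and expected
specificity ``1 - p_irrelevant``, giving closed-form oracles for the metric
and development machinery.

The filler vocabulary is constructed to be prefix-disjoint from every profile
term token, so a profile term matches a record if and only if it was inserted
— the oracles are exact, not approximate.

Defaults mirror the reference-set structure of the paramedic filter study:
431 relevant of 2102 records (20.5 % prevalence) and a candidate pool whose
single terms are mostly low-sensitivity / high-specificity.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .filterlang import FilterTerm, tokenize
from .records import (
    IRRELEVANT,
    RELEVANT,
    BibRecord,
    Corpus,
    GoldStandard,
    write_label_csv,
    write_medline,
)

DEFAULT_N_RELEVANT = 431
DEFAULT_N_IRRELEVANT = 1671

_JOURNALS = (
    "Emergency Medicine Australasia",
    "Resuscitation",
    "Prehospital Emergency Care",
    "Prehospital and Disaster Medicine",
    "Air Medical Journal",
    "European Journal of Emergency Medicine",
)
_YEARS = (2006, 2009, 2012, 2015)
_SH_QUALIFIERS = ("", "/education", "/methods", "/standards")
_TRUNC_SUFFIXES = ("", "s", "s", "ine")


@dataclass(frozen=True)
class TermProfile:
    """Class-conditional occurrence model for one candidate term.

    ``placement`` weights where an inserted occurrence lands; subject-heading
    terms can only be placed in the MeSH field and text-word terms never are.
    """

    term: FilterTerm
    p_relevant: float
    p_irrelevant: float
    placement: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for p in (self.p_relevant, self.p_irrelevant):
            if not 0.0 <= p <= 1.0:
                raise ValueError("occurrence probabilities must lie in [0, 1]")
        placement = self.placement or self.default_placement()
        if self.term.field == "sh":
            if set(placement) != {"mesh"}:
                raise ValueError("sh terms place only in the mesh field")
        else:
            if "mesh" in placement:
                raise ValueError("tw terms never place in the mesh field")
        total = sum(placement.values())
        if total <= 0:
            raise ValueError("placement weights must sum to a positive value")
        object.__setattr__(
            self, "placement", {k: v / total for k, v in placement.items()}
        )

    def default_placement(self) -> dict[str, float]:
        if self.term.field == "sh":
            return {"mesh": 1.0}
        return {"title": 0.3, "abstract": 0.7}


@dataclass
class CorpusSpec:
    """Recipe for one synthetic reference set; ``seed`` is mandatory so every
    corpus is exactly reproducible (same seed, byte-identical files)."""

    seed: int
    n_relevant: int = DEFAULT_N_RELEVANT
    n_irrelevant: int = DEFAULT_N_IRRELEVANT
    profiles: list[TermProfile] = field(default_factory=list)
    filler_vocabulary_size: int = 400

    def __post_init__(self) -> None:
        if self.n_relevant < 0 or self.n_irrelevant < 0:
            raise ValueError("class counts must be non-negative")
        if self.filler_vocabulary_size < 10:
            raise ValueError("filler vocabulary must hold at least 10 words")


def expected_single_term_performance(profile: TermProfile) -> tuple[float, float]:
    """Closed-form oracle: (expected sensitivity, expected specificity) of the
    profile's term run as a single-term filter."""
    return profile.p_relevant, 1.0 - profile.p_irrelevant


def _profile_prefixes(profiles: list[TermProfile]) -> set[str]:
    toks: set[str] = set()
    for prof in profiles:
        toks.update(prof.term.tokens)
        for suffix in _TRUNC_SUFFIXES:
            toks.update(t + suffix for t in prof.term.tokens)
    return toks


def _make_vocabulary(
    rng: np.random.Generator, size: int, profiles: list[TermProfile]
) -> list[str]:
    """Neutral filler words, prefix-disjoint from every profile term token."""
    forbidden = _profile_prefixes(profiles)
    letters = np.array(list(string.ascii_lowercase))
    vocab: list[str] = []
    seen: set[str] = set()
    while len(vocab) < size:
        length = int(rng.integers(5, 10))
        word = "".join(rng.choice(letters, size=length))
        if word in seen:
            continue
        if any(word.startswith(t) or t.startswith(word) for t in forbidden):
            continue
        seen.add(word)
        vocab.append(word)
    return vocab


def _surface_form(term: FilterTerm, rng: np.random.Generator) -> str:
    """Text inserted into a title/abstract for one occurrence of a tw term.

    Truncated terms occasionally get a suffix on the final token (still a
    prefix match); exact terms are inserted verbatim.
    """
    text = term.text
    if term.truncated:
        text += str(rng.choice(_TRUNC_SUFFIXES))
    return text


def generate_corpus(spec: CorpusSpec) -> tuple[Corpus, GoldStandard]:
    """Generate a labelled corpus per the spec; reproducible from the seed.

    Prevalence is exact by construction (counts, not sampling): the first
    ``n_relevant`` sequential ids are the relevant class.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = np.array(_make_vocabulary(rng, spec.filler_vocabulary_size, spec.profiles))
    mesh_filler = [
        " ".join(w.capitalize() for w in rng.choice(vocab, size=2)) for _ in range(40)
    ]

    corpus = Corpus(provenance=f"synthetic corpus (seed={spec.seed})")
    labels: dict[str, str] = {}
    total = spec.n_relevant + spec.n_irrelevant
    for i in range(total):
        is_relevant = i < spec.n_relevant
        record_id = f"S{i + 1:06d}"
        title_words = list(rng.choice(vocab, size=int(rng.integers(4, 9))))
        abstract_words = list(rng.choice(vocab, size=int(rng.integers(20, 51))))
        headings = list(rng.choice(mesh_filler, size=int(rng.integers(1, 4)), replace=False))

        for prof in spec.profiles:
            p = prof.p_relevant if is_relevant else prof.p_irrelevant
            if rng.random() >= p:
                continue
            slots = list(prof.placement)
            weights = [prof.placement[s] for s in slots]
            slot = slots[int(rng.choice(len(slots), p=weights))]
            if slot == "mesh":
                headings.append(
                    prof.term.text.title() + str(rng.choice(_SH_QUALIFIERS))
                )
            elif slot == "title":
                pos = int(rng.integers(0, len(title_words) + 1))
                title_words.insert(pos, _surface_form(prof.term, rng))
            else:
                pos = int(rng.integers(0, len(abstract_words) + 1))
                abstract_words.insert(pos, _surface_form(prof.term, rng))

        corpus.add(
            BibRecord(
                record_id=record_id,
                title=" ".join(title_words).capitalize() + ".",
                abstract=" ".join(abstract_words).capitalize() + ".",
                mesh_headings=headings,
                journal=str(rng.choice(_JOURNALS)),
                year=int(rng.choice(_YEARS)),
            )
        )
        labels[record_id] = RELEVANT if is_relevant else IRRELEVANT

    return corpus, GoldStandard(labels)


def write_corpus(
    corpus: Corpus, gold: GoldStandard, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Emit the corpus as a MEDLINE tagged file plus a label CSV — exactly the
    pair of inputs the records module consumes.  Returns the two paths."""
    prefix = Path(out_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    medline_path = prefix.with_suffix(".medline.txt")
    labels_path = prefix.with_suffix(".labels.csv")
    write_medline(corpus, medline_path)
    write_label_csv(gold, labels_path)
    return medline_path, labels_path


def default_term_profiles() -> list[TermProfile]:
    """A realistic candidate pool mirroring the paramedic-hedge vocabulary.

    Occurrence rates are set so single terms behave the way hedge studies
    find them: mostly low sensitivity with high specificity, a couple of
    broad terms, and two hyphen-variant spellings of the same concept.
    """
    t = FilterTerm

    def prof(term: FilterTerm, p_rel: float, p_irr: float) -> TermProfile:
        return TermProfile(term=term, p_relevant=p_rel, p_irrelevant=p_irr)

    return [
        prof(t("paramedic", "tw", truncated=True), 0.45, 0.03),
        prof(t("ems", "tw"), 0.15, 0.02),
        prof(t("emt", "tw"), 0.08, 0.01),
        prof(t("prehospital", "tw"), 0.25, 0.08),
        prof(t("pre-hospital", "tw"), 0.10, 0.04),
        prof(t("ambulance", "tw", truncated=True), 0.20, 0.05),
        prof(t("first responder", "tw", truncated=True), 0.05, 0.01),
        prof(t("hems", "tw"), 0.03, 0.01),
        prof(t("field triage", "tw"), 0.02, 0.004),
        prof(t("out-of-hospital", "tw"), 0.12, 0.06),
        prof(t("emergency services", "tw"), 0.05, 0.02),
        prof(t("emergency medical technicians", "tw"), 0.06, 0.01),
        prof(t("ambulances", "sh"), 0.18, 0.03),
        prof(t("emergency medical technicians", "sh"), 0.12, 0.01),
        prof(t("air ambulances", "sh"), 0.03, 0.005),
        prof(t("emergency medical services", "sh"), 0.30, 0.10),
    ]


def default_corpus_spec(seed: int) -> CorpusSpec:
    """The study-sized default: 431 relevant + 1671 irrelevant records over
    the default candidate pool."""
    return CorpusSpec(seed=seed, profiles=default_term_profiles())
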