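"""Bibliographic records, corpora, and gold-standard label bookkeeping.

Records are MEDLINE-style citations (PMID, title, abstract, MeSH headings,
journal, year).  A :class:`Corpus` is an id-keyed collection of records; a
:class:`GoldStandard` maps every record id in a screened corpus to a
relevant/irrelevant label.  Reading of the MEDLINE tagged export format is
delegated to ``Bio.Medline``; writing is implemented here since Biopython
provides no writer.
"""

from __future__ import annotations

import csv
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, TextIO

from Bio import Medline

RELEVANT = "relevant"
IRRELEVANT = "irrelevant"

_YEAR_RE = re.compile(r"\d{4}")
_TITLE_NORM_RE = re.compile(r"[^0-9a-z]+")


class DuplicateRecordError(ValueError):
    """Two records with the same record id in one source."""


class ConflictingLabelError(ValueError):
    """The same reviewer assigned two different labels to one record."""


class IncompleteGoldStandardError(ValueError):
    """A corpus record is missing a relevance label (screening incomplete)."""


@dataclass
class BibRecord:
    """One bibliographic record.

    ``record_id`` is the PMID when the record comes from MEDLINE, otherwise
    any opaque unique string.  ``mesh_headings`` are the assigned MeSH
    headings, each optionally carrying an Ovid-style ``/qualifier`` suffix.
    """

    record_id: str
    title: str = ""
    abstract: str = ""
    mesh_headings: list[str] = field(default_factory=list)
    journal: str = ""
    year: int | None = None

    def __post_init__(self) -> None:
        if not str(self.record_id).strip():
            raise ValueError("record_id must be non-empty")
        self.record_id = str(self.record_id).strip()
        self.mesh_headings = [h.strip() for h in self.mesh_headings if h.strip()]

    @property
    def has_abstract(self) -> bool:
        return bool(self.abstract.strip())


class Corpus:
    """An id-keyed collection of :class:`BibRecord` with unique ids."""

    def __init__(self, records: Iterable[BibRecord] = (), provenance: str = "") -> None:
        self.provenance = provenance
        self._records: dict[str, BibRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: BibRecord) -> None:
        if record.record_id in self._records:
            raise DuplicateRecordError(
                f"duplicate record_id {record.record_id!r}"
            )
        self._records[record.record_id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[BibRecord]:
        return iter(self._records.values())

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._records

    def __getitem__(self, record_id: str) -> BibRecord:
        return self._records[record_id]

    def ids(self) -> set[str]:
        return set(self._records)

    def __repr__(self) -> str:  # pragma: no cover - debug aid
        return f"<Corpus of {len(self)} records>"


def _first_year(dp: str) -> int | None:
    m = _YEAR_RE.search(dp)
    return int(m.group()) if m else None


def read_medline(path: str | Path | TextIO) -> Corpus:
    """Read a MEDLINE tagged-format file into a :class:`Corpus`.

    Tags of interest: PMID, TI, AB, MH, JT/TA, DP.  Multi-line TI/AB values
    are joined with single spaces (Bio.Medline semantics).  A block without a
    PMID is rejected with a warning; a duplicate PMID raises
    :class:`DuplicateRecordError` naming the PMID.
    """
    if isinstance(path, (str, Path)):
        with open(path, encoding="utf-8") as handle:
            return _read_medline_handle(handle, provenance=str(path))
    return _read_medline_handle(path, provenance=getattr(path, "name", "<stream>"))


def _read_medline_handle(handle: TextIO, provenance: str) -> Corpus:
    corpus = Corpus(provenance=f"read_medline({provenance})")
    for raw in Medline.parse(handle):
        pmid = raw.get("PMID", "").strip()
        if not pmid:
            warnings.warn(
                "MEDLINE block without PMID rejected "
                f"(TI={raw.get('TI', '')[:40]!r})",
                stacklevel=2,
            )
            continue
        corpus.add(
            BibRecord(
                record_id=pmid,
                title=raw.get("TI", "").strip(),
                abstract=raw.get("AB", "").strip(),
                mesh_headings=list(raw.get("MH", [])),
                journal=(raw.get("JT") or raw.get("TA") or "").strip(),
                year=_first_year(raw.get("DP", "")),
            )
        )
    return corpus


def write_medline(corpus: Corpus, path: str | Path | TextIO) -> None:
    """Write a corpus in the MEDLINE tagged dialect that ``read_medline`` reads.

    Round trip preserves record_id, title, abstract and the MeSH heading list
    exactly (values are written on single, unwrapped lines).
    """
    if isinstance(path, (str, Path)):
        with open(path, "w", encoding="utf-8") as handle:
            _write_medline_handle(corpus, handle)
    else:
        _write_medline_handle(corpus, path)


def _write_medline_handle(corpus: Corpus, handle: TextIO) -> None:
    for rec in corpus:
        handle.write(f"PMID- {rec.record_id}\n")
        if rec.title:
            handle.write(f"TI  - {rec.title}\n")
        if rec.abstract:
            handle.write(f"AB  - {rec.abstract}\n")
        for heading in rec.mesh_headings:
            handle.write(f"MH  - {heading}\n")
        if rec.journal:
            handle.write(f"JT  - {rec.journal}\n")
        if rec.year is not None:
            handle.write(f"DP  - {rec.year}\n")
        handle.write("\n")


def _normalised_title_key(record: BibRecord) -> tuple[str, int | None]:
    title = _TITLE_NORM_RE.sub(" ", record.title.casefold()).strip()
    return title, record.year


def prepare_retrieval_set(corpus: Corpus) -> tuple[Corpus, dict[str, int]]:
    """Prepare a screened reference set: drop duplicates and abstract-less records.

    Duplicates are detected by record_id first (impossible within one
    :class:`Corpus`, but kept for merged inputs) and then by case-folded,
    punctuation-stripped title plus year, keeping the first occurrence.
    Records whose abstract is empty or whitespace-only are then removed.

    Returns the prepared corpus and an exclusion report
    ``{"duplicate": n, "no_abstract": n}``.
    """
    report = {"duplicate": 0, "no_abstract": 0}
    seen_titles: set[tuple[str, int | None]] = set()
    kept = Corpus(provenance=f"{corpus.provenance} | prepare_retrieval_set")
    for rec in corpus:
        key = _normalised_title_key(rec)
        if key[0] and key in seen_titles:
            report["duplicate"] += 1
            continue
        seen_titles.add(key)
        if not rec.has_abstract:
            report["no_abstract"] += 1
            continue
        kept.add(rec)
    return kept, report


@dataclass(frozen=True)
class RelevanceLabel:
    """One reviewer's relevance judgement for one record."""

    record_id: str
    label: str
    reviewer: str = ""

    def __post_init__(self) -> None:
        if self.label not in (RELEVANT, IRRELEVANT):
            raise ValueError(
                f"label must be {RELEVANT!r} or {IRRELEVANT!r}, got {self.label!r}"
            )


@dataclass
class GoldStandard:
    """Complete record_id -> relevant/irrelevant mapping from screening."""

    labels: dict[str, str]

    def __post_init__(self) -> None:
        for rid, lab in self.labels.items():
            if lab not in (RELEVANT, IRRELEVANT):
                raise ValueError(f"invalid label {lab!r} for record {rid!r}")

    @property
    def relevant_ids(self) -> set[str]:
        return {r for r, v in self.labels.items() if v == RELEVANT}

    @property
    def irrelevant_ids(self) -> set[str]:
        return {r for r, v in self.labels.items() if v == IRRELEVANT}

    @property
    def n_relevant(self) -> int:
        return len(self.relevant_ids)

    @property
    def n_irrelevant(self) -> int:
        return len(self.irrelevant_ids)

    def ids(self) -> set[str]:
        return set(self.labels)

    def __len__(self) -> int:
        return len(self.labels)

    def validate_complete(self, corpus: Corpus) -> None:
        """Check the screening invariant: every corpus record has exactly one
        label and every label points at a corpus record.  The performance
        metrics assume a fully screened reference set, so a gap is an error."""
        missing = corpus.ids() - self.ids()
        extra = self.ids() - corpus.ids()
        if missing:
            raise IncompleteGoldStandardError(
                f"{len(missing)} corpus record(s) unscreened, e.g. "
                f"{sorted(missing)[:5]}"
            )
        if extra:
            raise IncompleteGoldStandardError(
                f"{len(extra)} label(s) without a corpus record, e.g. "
                f"{sorted(extra)[:5]}"
            )


def read_label_csv(path: str | Path, reviewer: str = "") -> list[RelevanceLabel]:
    """Read relevance labels from delimited text (record_id,label[,reviewer]).

    The first row is a header.  Labels are case-insensitive
    "relevant"/"irrelevant"; commas or tabs both work as delimiters.
    """
    labels: list[RelevanceLabel] = []
    with open(path, newline="", encoding="utf-8") as handle:
        sample = handle.read(4096)
        handle.seek(0)
        delimiter = "\t" if sample.count("\t") > sample.count(",") else ","
        reader = csv.reader(handle, delimiter=delimiter)
        next(reader, None)  # header
        for row in reader:
            if not row or not "".join(row).strip():
                continue
            rid = row[0].strip()
            lab = row[1].strip().casefold()
            rev = row[2].strip() if len(row) > 2 else reviewer
            labels.append(RelevanceLabel(rid, lab, rev))
    return labels


def write_label_csv(gold: GoldStandard | Mapping[str, str], path: str | Path) -> None:
    labels = gold.labels if isinstance(gold, GoldStandard) else dict(gold)
    with open(path, "w", newline="", encoding="utf-8") as handle:
        writer = csv.writer(handle)
        writer.writerow(["record_id", "label"])
        for rid in sorted(labels):
            writer.writerow([rid, labels[rid]])


def gold_standard_from_csv(path: str | Path) -> GoldStandard:
    labels = read_label_csv(path)
    merged: dict[str, str] = {}
    for lab in labels:
        if lab.record_id in merged and merged[lab.record_id] != lab.label:
            raise ConflictingLabelError(
                f"record {lab.record_id!r} carries conflicting labels in {path}"
            )
        merged[lab.record_id] = lab.label
    return GoldStandard(merged)


@dataclass
class ReconcileResult:
    """Outcome of dual independent screening before adjudication.

    ``agreed`` holds the labels both reviewers gave identically; ``conflicts``
    the ids they disagree on (for third-reviewer adjudication); ``only_a`` /
    ``only_b`` the ids screened by a single reviewer (reported, never guessed).
    """

    agreed: dict[str, str]
    conflicts: list[str]
    only_a: set[str]
    only_b: set[str]

    def complete(self, adjudications: Mapping[str, str]) -> GoldStandard:
        """Apply the third reviewer's decisions and return the gold standard."""
        unresolved = [c for c in self.conflicts if c not in adjudications]
        if unresolved:
            raise IncompleteGoldStandardError(
                f"unadjudicated conflict(s): {unresolved[:5]}"
            )
        labels = dict(self.agreed)
        for rid in self.conflicts:
            lab = adjudications[rid].casefold()
            if lab not in (RELEVANT, IRRELEVANT):
                raise ValueError(f"invalid adjudication {lab!r} for {rid!r}")
            labels[rid] = lab
        return GoldStandard(labels)


def _by_reviewer(labels: Iterable[RelevanceLabel], who: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for lab in labels:
        if lab.record_id in out and out[lab.record_id] != lab.label:
            raise ConflictingLabelError(
                f"reviewer {who} labelled record {lab.record_id!r} twice "
                f"with different values"
            )
        out[lab.record_id] = lab.label
    return out


def reconcile_labels(
    labels_a: Iterable[RelevanceLabel], labels_b: Iterable[RelevanceLabel]
) -> ReconcileResult:
    """Merge two independent screening passes.

    Agreements become final labels; disagreements are returned for
    adjudication.  The agreed set and the conflict list partition the ids
    screened by both reviewers.
    """
    a = _by_reviewer(labels_a, "A")
    b = _by_reviewer(labels_b, "B")
    shared = set(a) & set(b)
    agreed = {rid: a[rid] for rid in shared if a[rid] == b[rid]}
    conflicts = sorted(rid for rid in shared if a[rid] != b[rid])
    return ReconcileResult(
        agreed=agreed,
        conflicts=conflicts,
        only_a=set(a) - set(b),
        only_b=set(b) - set(a),
    )
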