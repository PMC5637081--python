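"""Contingency tables and diagnostic performance statistics for search filters.

Filter validation treats retrieval like a diagnostic test applied to a fully
screened reference set: each record is either relevant or irrelevant (gold
standard) and either retrieved or not (the filter).  The 2x2 table

    =================  =========  ===========
    ..                 relevant   irrelevant
    retrieved          a          b
    not retrieved      c          d
    =================  =========  ===========

yields sensitivity a/(a+c), specificity d/(b+d), precision a/(a+b),
NNR = 1/precision (number needed to read: records screened per relevant find)
and accuracy (a+d)/(a+b+c+d).
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass
from typing import Iterable, Sequence, TYPE_CHECKING

if TYPE_CHECKING:  # pragma: no cover
    from .filterlang import FilterExpr
    from .records import Corpus, GoldStandard


class UnscreenedRecordError(ValueError):
    """A retrieved id has no gold-standard label."""


@dataclass(frozen=True)
class ContingencyTable:
    """Counts a, b, c, d of the filter-vs-gold-standard 2x2 table."""

    a: int  # relevant, retrieved (true positives)
    b: int  # irrelevant, retrieved (false positives)
    c: int  # relevant, not retrieved (false negatives)
    d: int  # irrelevant, not retrieved (true negatives)

    def __post_init__(self) -> None:
        for name in "abcd":
            value = getattr(self, name)
            if not isinstance(value, int) or value < 0:
                raise ValueError(f"count {name} must be a non-negative integer")

    @property
    def retrieved(self) -> int:
        return self.a + self.b

    @property
    def relevant(self) -> int:
        return self.a + self.c

    @property
    def irrelevant(self) -> int:
        return self.b + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class PerformanceReport:
    """Raw (unrounded) performance statistics derived from one table.

    ``precision`` and ``nnr`` are ``None`` when the filter retrieved nothing
    (a+b = 0): both are then undefined, never 0 or infinity.
    """

    sensitivity: float
    specificity: float
    precision: float | None
    nnr: float | None
    accuracy: float
    table: ContingencyTable

    def format_row(self) -> dict[str, str]:
        """Display-rounded values: percentages to 1 dp, NNR to 2 dp."""
        return {
            "sensitivity": f"{100 * self.sensitivity:.1f}%",
            "specificity": f"{100 * self.specificity:.1f}%",
            "precision": "undefined" if self.precision is None else f"{self.precision:.3f}",
            "nnr": "undefined" if self.nnr is None else f"{self.nnr:.2f}",
            "accuracy": f"{100 * self.accuracy:.1f}%",
        }


def contingency(retrieved: Iterable[str], gold: "GoldStandard") -> ContingencyTable:
    """Build the 2x2 table from a retrieval set and the gold standard.

    Every retrieved id must carry a label (the metrics are defined only over
    the screened reference set); an unlabelled id raises
    :class:`UnscreenedRecordError` naming it.
    """
    retrieved_set = set(retrieved)
    relevant = gold.relevant_ids
    irrelevant = gold.irrelevant_ids
    outside = retrieved_set - relevant - irrelevant
    if outside:
        raise UnscreenedRecordError(
            f"retrieved id(s) outside the gold standard: {sorted(outside)[:5]}"
        )
    a = len(retrieved_set & relevant)
    b = len(retrieved_set & irrelevant)
    return ContingencyTable(a=a, b=b, c=len(relevant) - a, d=len(irrelevant) - b)


def performance(table: ContingencyTable) -> PerformanceReport:
    """Sensitivity, specificity, precision, NNR and accuracy for one table.

    Requires at least one relevant and one irrelevant record in the reference
    set (a+c > 0 and b+d > 0), otherwise sensitivity/specificity are
    undefined and a ValueError is raised.
    """
    if table.relevant == 0 or table.irrelevant == 0:
        raise ValueError(
            "performance requires a+c > 0 and b+d > 0 "
            f"(got relevant={table.relevant}, irrelevant={table.irrelevant})"
        )
    precision = table.a / table.retrieved if table.retrieved else None
    nnr = 1.0 / precision if precision else None
    return PerformanceReport(
        sensitivity=table.a / table.relevant,
        specificity=table.d / table.irrelevant,
        precision=precision,
        nnr=nnr,
        accuracy=(table.a + table.d) / table.total,
        table=table,
    )


def _round_half_up(x: float) -> int:
    return math.floor(x + 0.5)


def reconstruct_table(
    n_relevant: int, n_irrelevant: int, sensitivity: float, specificity: float
) -> ContingencyTable:
    """Invert the performance formulas: rebuild the 2x2 table from class sizes
    and (possibly display-rounded) sensitivity/specificity.

    a and d are rounded half-up to the nearest integer; used to audit
    published filter rows for internal consistency.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must lie in [0, 1]")
    if n_relevant <= 0 or n_irrelevant <= 0:
        raise ValueError("class sizes must be positive")
    a = _round_half_up(n_relevant * sensitivity)
    d = _round_half_up(n_irrelevant * specificity)
    return ContingencyTable(a=a, b=n_irrelevant - d, c=n_relevant - a, d=d)


def evaluate_performance(
    expr: "FilterExpr", corpus: "Corpus", gold: "GoldStandard"
) -> PerformanceReport:
    """Run a filter over a fully screened corpus and score it.

    Convenience wrapper: validates that the gold standard completely covers
    the corpus, retrieves, and computes the performance report.
    """
    from .filterlang import retrieve

    gold.validate_complete(corpus)
    return performance(contingency(retrieve(expr, corpus), gold))


@dataclass(frozen=True)
class SingleTermSummary:
    """Mean/SD of single-term sensitivity and specificity (percent scale) and
    the NNR range over terms with a defined NNR."""

    n_terms: int
    mean_sensitivity_pct: float
    sd_sensitivity_pct: float | None
    mean_specificity_pct: float
    sd_specificity_pct: float | None
    nnr_min: float | None
    nnr_max: float | None
    n_defined_nnr: int

    def format(self) -> str:
        sd_sens = "n/a" if self.sd_sensitivity_pct is None else f"{self.sd_sensitivity_pct:.1f}"
        sd_spec = "n/a" if self.sd_specificity_pct is None else f"{self.sd_specificity_pct:.1f}"
        nnr = (
            "undefined"
            if self.nnr_min is None
            else f"{self.nnr_min:.2f}-{self.nnr_max:.2f}"
        )
        return (
            f"{self.n_terms} terms: mean sensitivity "
            f"{self.mean_sensitivity_pct:.1f}% (SD {sd_sens}), mean specificity "
            f"{self.mean_specificity_pct:.1f}% (SD {sd_spec}), NNR range {nnr}"
        )


def summarize_single_terms(reports: Sequence[PerformanceReport]) -> SingleTermSummary:
    """Summarise a single-term analysis the way hedge studies report it.

    Sample standard deviation (n-1 denominator); ``None`` when only one term
    was analysed.  NNR min/max are taken over reports whose NNR is defined.
    """
    if not reports:
        raise ValueError("summarize_single_terms requires at least one report")
    sens = [100 * r.sensitivity for r in reports]
    spec = [100 * r.specificity for r in reports]
    nnrs = [r.nnr for r in reports if r.nnr is not None]
    many = len(reports) > 1
    return SingleTermSummary(
        n_terms=len(reports),
        mean_sensitivity_pct=statistics.fmean(sens),
        sd_sensitivity_pct=statistics.stdev(sens) if many else None,
        mean_specificity_pct=statistics.fmean(spec),
        sd_specificity_pct=statistics.stdev(spec) if many else None,
        nnr_min=min(nnrs) if nnrs else None,
        nnr_max=max(nnrs) if nnrs else None,
        n_defined_nnr=len(nnrs),
    )
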