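"""The published paramedic/prehospital search filters and consistency audits.

Ships the two paramedic hedges (sensitivity- and specificity-maximising) as
verbatim Ovid strings with their reported performance, plus the performance
row of the older prehospital filter (whose query string is published
elsewhere and is not redistributed here — only its reported figures are
packaged, for auditing).

``check_published`` rebuilds each filter's 2x2 table from the reference-set
class sizes and the reported sensitivity/specificity, recomputes the NNR and
compares it with the printed one.  A reported NNR printed as a whole number
is compared at integer precision (the study text quotes "a NNR of 2" for a
reconstructed 2.01); others at two decimals.  The prehospital row fails this
audit (reconstruction gives about 2.38 against a printed 2.44) and is
flagged, not silently reproduced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

from .filterlang import FilterExpr, parse_filter
from .metrics import performance, reconstruct_table

_DATA_FILE = "published_filters.json"


@dataclass(frozen=True)
class PublishedFilter:
    """One published filter: verbatim Ovid text (when available) plus the
    performance figures as printed."""

    name: str
    syntax: str
    ovid_text: str | None
    sensitivity: float
    specificity: float
    nnr: float

    def parse(self) -> FilterExpr:
        if self.ovid_text is None:
            raise ValueError(
                f"filter {self.name!r} has no packaged query string"
            )
        return parse_filter(self.ovid_text)


def _load() -> dict:
    payload = resources.files("hedgekit.data").joinpath(_DATA_FILE).read_text("utf-8")
    return json.loads(payload)


def reference_set_sizes() -> dict[str, int]:
    """Class sizes of the hand-screened reference set the filters were
    validated on (initial retrieval, screened, relevant, irrelevant)."""
    return dict(_load()["reference_set"])


def published_filters() -> dict[str, PublishedFilter]:
    out: dict[str, PublishedFilter] = {}
    for row in _load()["filters"]:
        perf = row["reported_performance"]
        out[row["name"]] = PublishedFilter(
            name=row["name"],
            syntax=row["syntax"],
            ovid_text=row["text"],
            sensitivity=perf["sensitivity"],
            specificity=perf["specificity"],
            nnr=perf["nnr"],
        )
    return out


def get_filter(name: str) -> PublishedFilter:
    filters = published_filters()
    try:
        return filters[name]
    except KeyError:
        raise KeyError(
            f"unknown published filter {name!r}; available: {sorted(filters)}"
        ) from None


@dataclass(frozen=True)
class ConsistencyCheck:
    """Audit of one published performance row against reconstruction."""

    name: str
    reported_nnr: float
    reconstructed_nnr: float
    consistent: bool
    detail: str


def _nnr_consistent(reported: float, reconstructed: float) -> bool:
    if round(reported, 2) == float(int(round(reported))):
        # whole-number printed NNR: integer precision
        return round(reconstructed) == round(reported)
    return abs(round(reconstructed, 2) - reported) < 0.005


def check_published() -> list[ConsistencyCheck]:
    """Audit every packaged filter row for internal consistency.

    Reconstructs a/b/c/d from the reference-set class sizes and the printed
    sensitivity/specificity, recomputes the NNR and compares it with the
    printed value at the printed precision.
    """
    sizes = reference_set_sizes()
    checks: list[ConsistencyCheck] = []
    for pf in published_filters().values():
        table = reconstruct_table(
            sizes["relevant"], sizes["irrelevant"], pf.sensitivity, pf.specificity
        )
        report = performance(table)
        assert report.nnr is not None
        ok = _nnr_consistent(pf.nnr, report.nnr)
        detail = (
            f"reconstructed table a={table.a} b={table.b} c={table.c} d={table.d}; "
            f"NNR {report.nnr:.2f} vs reported {pf.nnr:.2f}: "
            + ("consistent" if ok else "INCONSISTENT")
        )
        checks.append(
            ConsistencyCheck(
                name=pf.name,
                reported_nnr=pf.nnr,
                reconstructed_nnr=report.nnr,
                consistent=ok,
                detail=detail,
            )
        )
    return checks
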