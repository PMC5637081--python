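"""Single-term analysis and iterative OR-filter construction.

Hedge development proceeds in two stages.  First every candidate term is
scored on its own against the gold standard (*single-term analysis*).  High
performing terms are then OR-combined; terms are added and subtracted from
trial filters until performance stops improving, once favouring sensitivity
(broad filters for researchers) and once favouring specificity (low-NNR
filters for clinicians).  The add/subtract iteration is formalised here as a
deterministic greedy forward selection with backward pruning; an exhaustive
small-pool search is provided so the greedy result can be audited against the
true optimum.

Because the built filters are pure OR-combinations, adding a term can only
raise sensitivity and lower specificity.  The two objectives are therefore
constrained mirror images: sensitivity-maximising adds terms while
specificity stays at or above a floor; specificity-maximising adds the
cheapest terms (least specificity loss) until sensitivity reaches its floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .filterlang import FilterExpr, FilterTerm, Or, retrieve, serialize_filter
from .metrics import PerformanceReport, contingency, performance
from .records import Corpus, GoldStandard

SENSITIVITY_MAXIMISING = "sensitivity_maximising"
SPECIFICITY_MAXIMISING = "specificity_maximising"
_OBJECTIVES = (SENSITIVITY_MAXIMISING, SPECIFICITY_MAXIMISING)


class InfeasibleFloorError(ValueError):
    """No filter from the pool can satisfy the configured floor."""


@dataclass(frozen=True)
class SingleTermResult:
    """Performance of one candidate term run as a one-term filter."""

    term: FilterTerm
    report: PerformanceReport

    @property
    def sort_key(self) -> tuple:
        return (-self.report.sensitivity, -self.report.specificity, self.term.text)


def single_term_analysis(
    pool: Sequence[FilterTerm], corpus: Corpus, gold: GoldStandard
) -> list[SingleTermResult]:
    """Score every pool term individually against the gold standard.

    Results are sorted by descending sensitivity, ties broken by descending
    specificity then term text.
    """
    if not pool:
        raise ValueError("single_term_analysis requires a non-empty pool")
    gold.validate_complete(corpus)
    results = [
        SingleTermResult(term, performance(contingency(retrieve(term, corpus), gold)))
        for term in pool
    ]
    return sorted(results, key=lambda r: r.sort_key)


@dataclass
class DevelopmentConfig:
    """Configuration of the greedy OR-filter builder.

    ``objective`` selects which metric is maximised; ``floor`` is the minimum
    acceptable value of the *other* metric (a specificity floor when
    maximising sensitivity, and vice versa).  ``seed`` is accepted for API
    stability but the builder is fully deterministic: ties are broken by
    greater improvement of the non-objective metric, then fewer retrieved
    records, then term text.
    """

    candidate_pool: list[FilterTerm]
    objective: str = SENSITIVITY_MAXIMISING
    floor: float = 0.0
    max_terms: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in _OBJECTIVES:
            raise ValueError(f"objective must be one of {_OBJECTIVES}")
        if not 0.0 <= self.floor <= 1.0:
            raise ValueError("floor must lie in [0, 1]")
        if self.max_terms < 1:
            raise ValueError("max_terms must be >= 1")
        if not self.candidate_pool:
            raise ValueError("candidate_pool must be non-empty")


@dataclass(frozen=True)
class TraceStep:
    """One add/subtract step of the greedy iteration."""

    action: str  # "add" | "remove"
    term: FilterTerm
    sensitivity_before: float
    specificity_before: float
    sensitivity_after: float
    specificity_after: float
    n_retrieved_after: int


@dataclass
class DevelopmentResult:
    """Outcome of a greedy development run.

    ``expr`` is ``None`` only when the run was infeasible (``feasible`` is
    False and ``stop_reason`` explains why).  ``trace`` replays to ``expr``:
    applying its add/remove steps to an empty term list reproduces the
    returned filter exactly.
    """

    expr: FilterExpr | None
    terms: list[FilterTerm]
    trace: list[TraceStep]
    report: PerformanceReport | None
    feasible: bool
    stop_reason: str
    objective: str
    notes: list[str] = field(default_factory=list)

    def replay(self) -> list[FilterTerm]:
        terms: list[FilterTerm] = []
        for step in self.trace:
            if step.action == "add":
                terms.append(step.term)
            else:
                terms.remove(step.term)
        return terms

    def serialize(self) -> str:
        if self.expr is None:
            return ""
        return serialize_filter(self.expr)


def _or_expr(terms: Sequence[FilterTerm]) -> FilterExpr | None:
    if not terms:
        return None
    if len(terms) == 1:
        return terms[0]
    return Or(*terms)


def _metrics_for(
    ids: frozenset[str], relevant: frozenset[str], irrelevant: frozenset[str]
) -> tuple[float, float]:
    sens = len(ids & relevant) / len(relevant)
    spec = 1.0 - len(ids & irrelevant) / len(irrelevant)
    return sens, spec


def greedy_develop(
    config: DevelopmentConfig, corpus: Corpus, gold: GoldStandard
) -> DevelopmentResult:
    """Greedy forward selection with backward pruning of OR-filters.

    Starting from the empty filter, the candidate whose addition most
    improves the objective metric is OR-added (ties: greater improvement in
    the non-objective metric, then fewer retrieved records, then term text);
    while the non-objective metric is still below its floor, additions that
    raise it are accepted even when the objective cannot improve (this is
    what drives the specificity-maximising variant, whose objective can only
    fall as OR-terms accumulate).  After each addition any term whose removal
    does not reduce the objective and raises the non-objective is subtracted.
    The run stops when no acceptable addition exists or ``max_terms`` is
    reached; a floor no filter can honour yields an explicit infeasible
    result rather than a silent empty filter.
    """
    gold.validate_complete(corpus)
    relevant = frozenset(gold.relevant_ids)
    irrelevant = frozenset(gold.irrelevant_ids)
    if not relevant or not irrelevant:
        raise ValueError("gold standard must contain both classes")

    sens_objective = config.objective == SENSITIVITY_MAXIMISING

    def split(sens: float, spec: float) -> tuple[float, float]:
        """(objective, non-objective) view of the metric pair."""
        return (sens, spec) if sens_objective else (spec, sens)

    term_sets: dict[FilterTerm, frozenset[str]] = {
        t: frozenset(retrieve(t, corpus)) for t in config.candidate_pool
    }

    chosen: list[FilterTerm] = []
    current: frozenset[str] = frozenset()
    trace: list[TraceStep] = []
    stop_reason = "no_improvement"

    while True:
        if len(chosen) >= config.max_terms:
            stop_reason = "max_terms"
            break
        cur_sens, cur_spec = _metrics_for(current, relevant, irrelevant)
        cur_obj, cur_non = split(cur_sens, cur_spec)

        best = None  # (delta_obj, delta_non, -n_retrieved, term sort text)
        for term in config.candidate_pool:
            if term in chosen:
                continue
            new = current | term_sets[term]
            if new == current:
                continue
            sens, spec = _metrics_for(new, relevant, irrelevant)
            obj, non = split(sens, spec)
            # never let an above-floor non-objective fall below the floor
            if cur_non >= config.floor and non < config.floor:
                continue
            improves_obj = obj > cur_obj
            seeks_floor = cur_non < config.floor and non > cur_non
            if not (improves_obj or seeks_floor):
                continue
            key = (obj - cur_obj, non - cur_non, -len(new), term.text)
            cand = (key, term, new, sens, spec)
            if best is None or _better(key, best[0]):
                best = cand

        if best is None:
            cur_obj, cur_non = split(*_metrics_for(current, relevant, irrelevant))
            if cur_non < config.floor:
                stop_reason = "infeasible_floor"
            break

        _, term, new, sens, spec = best
        trace.append(
            TraceStep(
                "add", term, cur_sens, cur_spec, sens, spec, len(new)
            )
        )
        chosen.append(term)
        current = new

        # backward pruning ("subtracted from trial filters")
        pruned = True
        while pruned and len(chosen) > 1:
            pruned = False
            cur_sens, cur_spec = _metrics_for(current, relevant, irrelevant)
            cur_obj, cur_non = split(cur_sens, cur_spec)
            for t in list(chosen):
                reduced = frozenset().union(
                    *(term_sets[u] for u in chosen if u is not t)
                )
                r_sens, r_spec = _metrics_for(reduced, relevant, irrelevant)
                r_obj, r_non = split(r_sens, r_spec)
                if r_obj >= cur_obj and r_non > cur_non and not (
                    cur_non >= config.floor and r_non < config.floor
                ):
                    trace.append(
                        TraceStep(
                            "remove", t, cur_sens, cur_spec, r_sens, r_spec, len(reduced)
                        )
                    )
                    chosen.remove(t)
                    current = reduced
                    pruned = True
                    break

    feasible = stop_reason != "infeasible_floor" and bool(chosen)
    if not chosen and stop_reason == "no_improvement":
        # empty result: either every term retrieves nothing, or the floor
        # rejected every candidate outright
        any_rejected_by_floor = any(
            split(*_metrics_for(term_sets[t], relevant, irrelevant))[1] < config.floor
            for t in config.candidate_pool
        )
        if any_rejected_by_floor:
            stop_reason = "infeasible_floor"
        feasible = False

    expr = _or_expr(chosen)
    report = (
        performance(contingency(current, gold)) if expr is not None else None
    )
    return DevelopmentResult(
        expr=expr,
        terms=list(chosen),
        trace=trace,
        report=report,
        feasible=feasible,
        stop_reason=stop_reason,
        objective=config.objective,
    )


def _better(key_a: tuple, key_b: tuple) -> bool:
    """Candidate ordering: larger deltas and fewer retrieved win; the term
    text component is compared ascending (lexicographically smaller wins)."""
    for a, b, ascending in zip(
        key_a, key_b, (False, False, False, True)
    ):
        if a == b:
            continue
        return (a < b) if ascending else (a > b)
    return False


def exhaustive_or_search(
    pool: Sequence[FilterTerm],
    corpus: Corpus,
    gold: GoldStandard,
    objective: str = SENSITIVITY_MAXIMISING,
    floor: float = 0.0,
    max_terms: int = 4,
) -> tuple[list[FilterTerm], float]:
    """Best OR-subset of the pool by exhaustive enumeration (small pools only).

    Returns the winning term list and its objective value; used to audit the
    greedy builder.  Subsets violating the floor on the non-objective metric
    are excluded; ties prefer the better non-objective value, then fewer
    terms, then term texts.
    """
    if objective not in _OBJECTIVES:
        raise ValueError(f"objective must be one of {_OBJECTIVES}")
    relevant = frozenset(gold.relevant_ids)
    irrelevant = frozenset(gold.irrelevant_ids)
    term_sets = {t: frozenset(retrieve(t, corpus)) for t in pool}
    sens_objective = objective == SENSITIVITY_MAXIMISING

    best_key = None
    best_terms: list[FilterTerm] = []
    best_obj = float("-inf")
    for k in range(1, max_terms + 1):
        for subset in combinations(pool, k):
            ids = frozenset().union(*(term_sets[t] for t in subset))
            sens, spec = _metrics_for(ids, relevant, irrelevant)
            obj, non = (sens, spec) if sens_objective else (spec, sens)
            if non < floor:
                continue
            key = (obj, non, -k, tuple(t.text for t in subset))
            if best_key is None or key > best_key:
                best_key = key
                best_terms = list(subset)
                best_obj = obj
    return best_terms, best_obj


def audit_against_exhaustive(
    result: DevelopmentResult,
    config: DevelopmentConfig,
    corpus: Corpus,
    gold: GoldStandard,
    max_terms: int = 4,
) -> float:
    """Compare a greedy result with the exhaustive optimum over small subsets
    and record the gap (exhaustive minus greedy objective) in the result's
    notes.  Returns the gap."""
    _, best_obj = exhaustive_or_search(
        config.candidate_pool, corpus, gold, config.objective, config.floor, max_terms
    )
    if result.report is None:
        greedy_obj = float("-inf")
    elif config.objective == SENSITIVITY_MAXIMISING:
        greedy_obj = result.report.sensitivity
    else:
        greedy_obj = result.report.specificity
    gap = best_obj - greedy_obj
    result.notes.append(
        f"exhaustive-search audit (subsets <= {max_terms} terms): "
        f"best objective {best_obj:.4f}, greedy {greedy_obj:.4f}, gap {gap:+.4f}"
    )
    return gap
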