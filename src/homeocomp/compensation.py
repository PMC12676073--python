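"""Group-level compensation calls, summaries and class comparison.

For each analyzable (line, group) mutation context, the statuses of the
group's homoeologs are read off the differential-expression results.  A
group counts as transcriptionally compensated when at least one
NON-mutated homoeolog is upregulated; the mutated homoeolog's own status
never triggers the flag.  Summaries report per-line proportions over
contexts and pooled proportions over unique group ids (a group compensated
in any line counts once in both numerator and denominator), separately for
the PTC and synonymous mutation classes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import stats

from .diffexp import DEResult, DOWN, NO_CHANGE, UP
from .genomodel import HomoeologGroup
from .variants import MutationContext, PTC, SYNONYMOUS

logger = logging.getLogger(__name__)

__all__ = [
    "GroupCompensationCall",
    "ClassSummary",
    "CompensationSummary",
    "ClassComparison",
    "call_group",
    "summarize",
    "compare_classes",
]

NOT_TESTED = "not_tested"


@dataclass(frozen=True)
class GroupCompensationCall:
    """Per-(line, group) compensation outcome."""

    line: str
    group_id: str
    mutation_class: str  # PTC or synonymous
    mutated_subgenome: str
    mutated_status: str | None  # up/down/no_change, None when untested
    homoeolog_statuses: Mapping[str, str]  # non-mutated subgenome -> status
    compensated: bool
    evaluable: bool = True

    def __post_init__(self) -> None:
        if self.mutation_class not in (PTC, SYNONYMOUS):
            raise ValueError(f"bad mutation class {self.mutation_class!r}")
        expect = any(
            s == UP for s in self.homoeolog_statuses.values()
        )
        if self.evaluable and self.compensated != expect:
            raise ValueError(
                "compensated flag inconsistent with homoeolog statuses"
            )


def call_group(
    context: MutationContext,
    group: HomoeologGroup,
    de_results: Mapping[str, DEResult],
) -> GroupCompensationCall:
    """Build the compensation call for one analyzable context.

    ``de_results`` maps gene id to its DE result for the context's line.
    Homoeologs without a usable result (missing, or untestable from zero
    expression) get status ``not_tested``; when the mutated homoeolog is
    missing, or every non-mutated homoeolog is untested, the call is
    flagged not evaluable.
    """
    if group.group_id != context.group_id:
        raise ValueError(
            f"context group {context.group_id!r} does not match "
            f"group {group.group_id!r}"
        )

    def status_of(gene: str) -> str | None:
        result = de_results.get(gene)
        if result is None or not np.isfinite(result.fold_change):
            return None
        return result.status

    mutated_status = status_of(context.mutated_gene)
    others = {
        sub: gene
        for sub, gene in group.members.items()
        if gene != context.mutated_gene
    }
    other_statuses = {sub: status_of(gene) for sub, gene in others.items()}

    evaluable = True
    if mutated_status is None:
        logger.debug(
            "(line=%s, group=%s): mutated homoeolog %s has no DE result",
            context.line, context.group_id, context.mutated_gene,
        )
        evaluable = False
    if all(s is None for s in other_statuses.values()):
        evaluable = False

    shown = {
        sub: (s if s is not None else NOT_TESTED)
        for sub, s in other_statuses.items()
    }
    compensated = evaluable and any(s == UP for s in other_statuses.values())
    return GroupCompensationCall(
        line=context.line,
        group_id=context.group_id,
        mutation_class=context.mutation_class,
        mutated_subgenome=context.mutated_subgenome,
        mutated_status=mutated_status if mutated_status is not None else NOT_TESTED,
        homoeolog_statuses=shown,
        compensated=compensated,
        evaluable=evaluable,
    )


@dataclass
class ClassSummary:
    """Counts and percentages for one mutation class at one scope."""

    n_contexts: int = 0
    n_mutated_down: int = 0
    n_mutated_up: int = 0
    n_compensated: int = 0
    n_unique_groups: int = 0
    n_unique_compensated: int = 0

    @property
    def pct_mutated_down(self) -> float:
        return _pct(self.n_mutated_down, self.n_contexts)

    @property
    def pct_compensated_contexts(self) -> float:
        return _pct(self.n_compensated, self.n_contexts)

    @property
    def pct_compensated_unique(self) -> float:
        return _pct(self.n_unique_compensated, self.n_unique_groups)

    def to_dict(self) -> dict:
        def _json(value: float):
            return None if np.isnan(value) else value

        return {
            "n_contexts": self.n_contexts,
            "n_mutated_down": self.n_mutated_down,
            "n_mutated_up": self.n_mutated_up,
            "n_compensated": self.n_compensated,
            "n_unique_groups": self.n_unique_groups,
            "n_unique_compensated": self.n_unique_compensated,
            "pct_mutated_down": _json(self.pct_mutated_down),
            "pct_compensated_contexts": _json(self.pct_compensated_contexts),
            "pct_compensated_unique": _json(self.pct_compensated_unique),
        }


def _pct(numerator: int, denominator: int) -> float:
    return 100.0 * numerator / denominator if denominator else float("nan")


@dataclass
class CompensationSummary:
    """Per-line and pooled compensation statistics per mutation class."""

    per_line: dict[str, dict[str, ClassSummary]] = field(default_factory=dict)
    pooled: dict[str, ClassSummary] = field(default_factory=dict)
    n_not_evaluable: int = 0

    def to_dict(self) -> dict:
        return {
            "per_line": {
                line: {cls: s.to_dict() for cls, s in classes.items()}
                for line, classes in self.per_line.items()
            },
            "pooled": {cls: s.to_dict() for cls, s in self.pooled.items()},
            "n_not_evaluable": self.n_not_evaluable,
        }


def summarize(calls: Iterable[GroupCompensationCall]) -> CompensationSummary:
    """Aggregate calls per line and pooled over unique group ids.

    Only evaluable calls enter the denominators.  In the pooled scope a
    group id counts once per class; it is compensated when compensated in
    at least one line.  The result is invariant to the order of ``calls``
    and idempotent under duplicated lines in the pooled unique counts.
    """
    calls = list(calls)
    if not calls:
        raise ValueError("summarize requires at least one call")
    summary = CompensationSummary()
    pooled_groups: dict[str, dict[str, bool]] = {PTC: {}, SYNONYMOUS: {}}
    for call in sorted(calls, key=lambda c: (c.line, c.group_id)):
        if not call.evaluable:
            summary.n_not_evaluable += 1
            continue
        line_stats = summary.per_line.setdefault(
            call.line, {PTC: ClassSummary(), SYNONYMOUS: ClassSummary()}
        )
        s = line_stats[call.mutation_class]
        s.n_contexts += 1
        if call.mutated_status == DOWN:
            s.n_mutated_down += 1
        elif call.mutated_status == UP:
            s.n_mutated_up += 1
        if call.compensated:
            s.n_compensated += 1
        seen = pooled_groups[call.mutation_class]
        seen[call.group_id] = seen.get(call.group_id, False) or call.compensated
    for cls, seen in pooled_groups.items():
        pooled = ClassSummary(
            n_unique_groups=len(seen),
            n_unique_compensated=sum(seen.values()),
        )
        for line_stats in summary.per_line.values():
            pooled.n_contexts += line_stats[cls].n_contexts
            pooled.n_mutated_down += line_stats[cls].n_mutated_down
            pooled.n_mutated_up += line_stats[cls].n_mutated_up
            pooled.n_compensated += line_stats[cls].n_compensated
        summary.pooled[cls] = pooled
    return summary


@dataclass(frozen=True)
class ClassComparison:
    """2x2 chi-squared comparison of compensation between mutation classes."""

    statistic: float
    pvalue: float
    dof: int
    table: tuple[tuple[int, int], tuple[int, int]]
    yates: bool
    low_expected: bool


def compare_classes(
    summary: CompensationSummary | Iterable[Iterable[int]],
    *,
    yates: bool = True,
) -> ClassComparison:
    """Pearson chi-squared (Yates-corrected by default) on the 2x2 table
    of compensated / not-compensated unique groups by PTC / synonymous
    class.  A plain 2x2 table may be passed instead of a summary.  Errors
    when either class has zero groups; warns when an expected cell < 5.
    """
    if isinstance(summary, CompensationSummary):
        rows = []
        for cls in (PTC, SYNONYMOUS):
            s = summary.pooled.get(cls)
            if s is None or s.n_unique_groups == 0:
                raise ValueError(
                    f"compare_classes needs >= 1 group in the {cls} class"
                )
            rows.append(
                (s.n_unique_compensated,
                 s.n_unique_groups - s.n_unique_compensated)
            )
        table = np.asarray(rows, dtype=float)
    else:
        table = np.asarray(summary, dtype=float)
        if table.shape != (2, 2):
            raise ValueError("expected a 2x2 table")
        if (table.sum(axis=1) == 0).any():
            raise ValueError("compare_classes needs >= 1 group in each class")

    if table.sum(axis=0).min() == 0:
        # degenerate column (e.g. no compensated group anywhere): no
        # association is estimable; report statistic 0, p = 1
        expected_low = True
        return ClassComparison(
            statistic=0.0, pvalue=1.0, dof=1,
            table=_as_int_table(table), yates=yates, low_expected=expected_low,
        )
    statistic, pvalue, dof, expected = stats.chi2_contingency(
        table, correction=yates
    )
    low = bool((expected < 5).any())
    if low:
        warnings.warn(
            "chi-squared expected cell count < 5; p-value may be unreliable",
            stacklevel=2,
        )
    return ClassComparison(
        statistic=float(statistic),
        pvalue=float(pvalue),
        dof=int(dof),
        table=_as_int_table(table),
        yates=yates,
        low_expected=low,
    )


def _as_int_table(table: np.ndarray) -> tuple[tuple[int, int], tuple[int, int]]:
    t = np.asarray(table)
    return ((int(t[0, 0]), int(t[0, 1])), (int(t[1, 0]), int(t[1, 1])))
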