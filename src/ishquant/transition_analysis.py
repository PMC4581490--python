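"""Expression-domain transition statistics across developmental stages.

For every gene with images at two or more stages, each pair of consecutive
*available* stages is classified against the three major expression regions:

``minor``
    expression present at both stages with an identical region set,
``major``
    present at both stages but the region set changed,
``appeared`` / ``vanished``
    expression absent at the first / second stage only,
``none``
    absent at both.

Classified pairs are tallied into an (initial stage x final stage) count
matrix, either for all genes (five categories) or restricted to genes whose
initial expression lies in exactly one region (three categories:
minor / major / vanished).  Because available stages need not be adjacent, a
pair observed between stages i and f is credited to *every* consecutive-stage
period lying between them when the matrix is aggregated into per-period sums
and integer percentages.  A two-tail Fisher's exact test on 2x2 tables of
such counts is provided via exact hypergeometric enumeration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .domain_model import (
    REGIONS,
    DomainTable,
    MajorRegionMap,
    Stage,
    StageRecord,
    map_domains_to_regions,
)

__all__ = [
    "CATEGORIES_ALL",
    "CATEGORIES_REGION",
    "TransitionEvent",
    "PairwiseCountMatrix",
    "PeriodSummary",
    "consecutive_available_pairs",
    "classify_transition",
    "build_pairwise_matrix",
    "aggregate_periods",
    "percent_tuple",
    "fisher_exact_two_tail",
    "period_change_rate",
]

CATEGORIES_ALL = ("minor", "major", "appeared", "vanished", "none")
CATEGORIES_REGION = ("minor", "major", "vanished")


@dataclass(frozen=True)
class TransitionEvent:
    """One classified change between a gene's consecutive available stages."""

    gene: str
    initial: Stage
    final: Stage
    category: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "initial", Stage.parse(self.initial))
        object.__setattr__(self, "final", Stage.parse(self.final))
        if self.initial >= self.final:
            raise ValueError("initial stage must precede final stage")
        if self.category not in CATEGORIES_ALL:
            raise ValueError(f"unknown category {self.category!r}")


@dataclass(frozen=True)
class PairwiseCountMatrix:
    """(initial stage x final stage) transition-category counts.

    ``filter`` is one of ``"R1"``, ``"R2"``, ``"R3"`` (initial expression in
    exactly that region; 3-tuples minor:major:vanished) or ``"all"`` (every
    pair; 5-tuples minor:major:appeared:vanished:none).  Only cells with
    final index > initial index are populated.
    """

    filter: str
    counts: dict

    def __post_init__(self) -> None:
        if self.filter not in REGIONS + ("all",):
            raise ValueError(f"filter must be one of {REGIONS + ('all',)}")
        k = len(self.categories)
        cleaned = {}
        for (i, f), tup in self.counts.items():
            i, f = Stage.parse(i), Stage.parse(f)
            tup = tuple(int(c) for c in tup)
            if i >= f:
                raise ValueError(f"cell ({i.label}, {f.label}): initial must precede final")
            if len(tup) != k or any(c < 0 for c in tup):
                raise ValueError(
                    f"cell ({i.label}, {f.label}) needs {k} nonnegative counts"
                )
            cleaned[(i, f)] = tup
        object.__setattr__(self, "counts", cleaned)

    @property
    def categories(self) -> tuple:
        return CATEGORIES_ALL if self.filter == "all" else CATEGORIES_REGION

    def get(self, initial: Stage, final: Stage) -> tuple:
        zero = (0,) * len(self.categories)
        return self.counts.get((Stage.parse(initial), Stage.parse(final)), zero)

    def total(self) -> int:
        return sum(sum(t) for t in self.counts.values())


@dataclass(frozen=True)
class PeriodSummary:
    """Per consecutive-stage period: summed counts and integer percentages."""

    filter: str
    categories: tuple
    counts: dict
    percentages: dict

    def periods(self) -> list:
        return sorted(self.counts)


def consecutive_available_pairs(
    records: Sequence[StageRecord],
) -> list:
    """(initial, final) record pairs over a gene's own availability order.

    Stages may be non-adjacent in the global stage order; only availability
    adjacency matters.
    """
    recs = sorted(records, key=lambda r: r.stage)
    return list(zip(recs, recs[1:]))


def classify_transition(regions_i: Iterable[str], regions_f: Iterable[str]) -> str:
    """Classify one stage-to-stage change from endpoint major-region sets."""
    ri, rf = frozenset(regions_i), frozenset(regions_f)
    for r in ri | rf:
        if r not in REGIONS:
            raise ValueError(f"unknown region {r!r}")
    if not ri and not rf:
        return "none"
    if not ri:
        return "appeared"
    if not rf:
        return "vanished"
    return "minor" if ri == rf else "major"


def build_pairwise_matrix(
    table: DomainTable,
    region_map: Optional[MajorRegionMap] = None,
    filter: str = "all",
) -> PairwiseCountMatrix:
    """Tally classified pairs of consecutive available stages.

    With a region filter r, only pairs whose initial region set is exactly
    {r} are counted (minor = still exactly {r}, vanished = empty, otherwise
    major).  A stage whose region set is empty *only because all its domains
    are unmapped* is ambiguous, so such pairs are skipped with a warning;
    an empty domain set, by contrast, means "not expressed".
    """
    if filter not in REGIONS + ("all",):
        raise ValueError(f"filter must be one of {REGIONS + ('all',)}")
    region_map = region_map or MajorRegionMap()
    counts: dict = {}
    k = len(CATEGORIES_ALL if filter == "all" else CATEGORIES_REGION)
    skipped = 0
    for gene in table.analyzable_genes():
        for rec_i, rec_f in consecutive_available_pairs(table.records[gene]):
            ri, un_i = map_domains_to_regions(rec_i.domains, region_map)
            rf, un_f = map_domains_to_regions(rec_f.domains, region_map)
            if (rec_i.domains and not ri and un_i) or (rec_f.domains and not rf and un_f):
                skipped += 1
                continue
            if filter == "all":
                cat = classify_transition(ri, rf)
                cats = CATEGORIES_ALL
            else:
                if ri != frozenset({filter}):
                    continue
                cat = classify_transition(ri, rf)
                if cat not in CATEGORIES_REGION:  # pragma: no cover - ri nonempty
                    continue
                cats = CATEGORIES_REGION
            key = (rec_i.stage, rec_f.stage)
            cell = list(counts.get(key, (0,) * k))
            cell[cats.index(cat)] += 1
            counts[key] = tuple(cell)
    if skipped:
        warnings.warn(
            f"{skipped} stage pair(s) skipped: expression described only by "
            "domains with no major-region assignment",
            stacklevel=2,
        )
    return PairwiseCountMatrix(filter, counts)


def percent_tuple(counts: Sequence[int]) -> tuple:
    """Integer percentages: round(count / total * 100), ties away from zero.

    A zero total yields all-zero percentages.
    """
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        return tuple(0 for _ in counts)
    return tuple(math.floor(c / total * 100 + 0.5) for c in counts)


def aggregate_periods(matrix: PairwiseCountMatrix) -> PeriodSummary:
    """Sum pairwise cells into consecutive-stage periods.

    A cell (initial i, final f) contributes its counts to every period
    (s, s+1) with index(i) <= s and index(f) >= s+1 — the change could have
    happened in any period the observation spans.
    """
    k = len(matrix.categories)
    sums = {
        (Stage(s), Stage(s + 1)): [0] * k for s in range(len(Stage) - 1)
    }
    for (i, f), tup in matrix.counts.items():
        for s in range(int(i), int(f)):
            cell = sums[(Stage(s), Stage(s + 1))]
            for j, c in enumerate(tup):
                cell[j] += c
    counts = {p: tuple(v) for p, v in sums.items()}
    percentages = {p: percent_tuple(v) for p, v in counts.items()}
    return PeriodSummary(matrix.filter, matrix.categories, counts, percentages)


def fisher_exact_two_tail(a: int, b: int, c: int, d: int) -> float:
    """Two-tail Fisher's exact test for the 2x2 table [[a, b], [c, d]].

    The p-value is the sum of hypergeometric probabilities of all tables with
    the observed margins whose probability does not exceed that of the
    observed table.  Computed with exact integer arithmetic: with fixed
    margins every table probability shares the denominator C(N, n), so
    inclusion is an exact comparison of integer numerators and no floating
    tolerance is involved.  Any table with a zero margin has probability 1.
    """
    table = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in table):
        raise ValueError("table entries must be nonnegative integers")
    a, b, c, d = (int(x) for x in table)
    n_total = a + b + c + d
    row1, col1 = a + b, a + c
    if n_total == 0 or row1 in (0, n_total) or col1 in (0, n_total):
        return 1.0
    lo = max(0, col1 - (n_total - row1))
    hi = min(row1, col1)
    weights = [
        math.comb(row1, x) * math.comb(n_total - row1, col1 - x)
        for x in range(lo, hi + 1)
    ]
    w_obs = weights[a - lo]
    num = sum(w for w in weights if w <= w_obs)
    return num / math.comb(n_total, col1)


def period_change_rate(summary: PeriodSummary, categories: Iterable[str]) -> dict:
    """Per period, the sum of the integer percentages of selected categories.

    E.g. ``{"major", "appeared"}`` measures how much expression is being
    re-decided rather than refined in each period.
    """
    categories = set(categories)
    unknown = categories - set(summary.categories)
    if unknown:
        raise ValueError(f"categories {sorted(unknown)} not in summary")
    idx = [summary.categories.index(c) for c in categories]
    return {
        period: sum(pcts[j] for j in idx)
        for period, pcts in summary.percentages.items()
    }
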