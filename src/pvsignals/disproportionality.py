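"""Frequentist disproportionality statistics and the combined signal rule.

Every drug–event pair in a spontaneous-report database defines a 2×2 table
over deduplicated cases::

                event   no event
    drug          a        b
    no drug       c        d        N = a + b + c + d

The reporting odds ratio ROR = ad/bc (Woolf log-scale confidence interval)
and the proportional reporting ratio PRR = [a/(a+b)] / [c/(c+d)] with its
Pearson χ² statistic are computed here; the Bayesian statistics (BCPNN IC,
MGPS EBGM) come from :mod:`pvsignals.empirical_bayes`.  A pair is called a
*signal* when at least one of the four algorithms meets its criterion:

* ROR:   a ≥ 3 and lower 95% CI of ROR > 1
* PRR:   a ≥ 3, PRR ≥ 2 and χ² ≥ 4
* BCPNN: IC025 > 0
* MGPS:  EBGM05 > 2

Zero cells leave ROR/PRR undefined (NaN) by default — the minimum-count
criterion makes continuity-corrected micro-signals irrelevant — but a
Haldane–Anscombe 0.5 correction is available for comparability with other
software.  The counting unit is always the case: a case with several
preferred terms in the same event group contributes one to ``a``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import empirical_bayes as eb
from .report_store import CaseReport
from .vocabulary import case_groups

__all__ = [
    "ContingencyCell",
    "SignalCriteria",
    "SignalResult",
    "build_contingency",
    "compute_ror",
    "compute_prr_chi2",
    "evaluate_signal_criteria",
    "compute_signal",
    "rank_drugs_for_event",
]


@dataclass(frozen=True)
class ContingencyCell:
    """2×2 counts for one drug×event pair over a deduplicated case store."""

    drug: str
    event: str
    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class SignalCriteria:
    """Thresholds of the four signal-detection algorithms (all configurable)."""

    min_count: int = 3
    ror_lo_gt: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_gt: float = 0.0
    ebgm05_gt: float = 2.0


@dataclass
class SignalResult:
    """All four algorithms' statistics for one cell, plus the signal flags.

    Undefined statistics (zero cells without Haldane correction, IC025 at
    a=0) are NaN and fail their flag.
    """

    drug: str
    event: str
    a: int
    ror: float = math.nan
    ror_lo: float = math.nan
    ror_hi: float = math.nan
    prr: float = math.nan
    chi2: float = math.nan
    ic: float = math.nan
    ic025: float = math.nan
    ebgm: float = math.nan
    ebgm05: float = math.nan
    flags: dict[str, bool] = field(default_factory=dict)
    overall_signal: bool = False


def compute_ror(
    cell: ContingencyCell, z: float = 1.96, haldane: bool = False
) -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf log-scale CI.

    Returns ``(ror, lo, hi)``; any zero cell yields NaNs unless ``haldane``
    adds 0.5 to every cell.
    """
    a, b, c, d = cell.a, cell.b, cell.c, cell.d
    if min(a, b, c, d) == 0:
        if not haldane:
            return math.nan, math.nan, math.nan
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    ror = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return ror, ror * math.exp(-z * se), ror * math.exp(z * se)


def compute_prr_chi2(
    cell: ContingencyCell, yates: bool = False, haldane: bool = False
) -> tuple[float, float]:
    """Proportional reporting ratio and Pearson χ² (optionally Yates-corrected).

    PRR is undefined (NaN) when a margin needed by its ratio is zero; χ² is
    undefined when any margin is zero.
    """
    a, b, c, d = cell.a, cell.b, cell.c, cell.d
    if haldane and min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    n = a + b + c + d
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        return math.nan, math.nan
    prr = (a / r1) / (c / r2) if c > 0 else math.nan
    diff = abs(a * d - b * c)
    if yates:
        diff = max(diff - n / 2, 0.0)
    chi2 = n * diff * diff / (r1 * r2 * c1 * c2)
    return prr, chi2


def build_contingency(
    store: Sequence[CaseReport],
    exposure: str | Iterable[str],
    event: str,
    roles: frozenset[str] | set[str] = frozenset({"PS"}),
    known_events: Iterable[str] | None = None,
) -> ContingencyCell:
    """2×2 table for an ingredient (or set of ingredients) × event group.

    ``store`` must be deduplicated and annotated (ingredients and groups
    filled by :func:`pvsignals.vocabulary.annotate_store`).  ``a`` counts
    distinct cases with ≥1 matching exposure under the role filter *and*
    ≥1 reaction in the event group; b, c, d follow by complement, so
    a+b+c+d equals the store size.  An event label absent from both
    ``known_events`` (when given) and the store is rejected.
    """
    if not store:
        raise ValueError("case store is empty")
    exposures = {exposure} if isinstance(exposure, str) else set(exposure)
    observed = {r.group for case in store for r in case.reactions if r.group}
    known = set(known_events) if known_events is not None else observed
    if event not in known and event not in observed:
        raise ValueError(f"unknown event label {event!r}")
    a = b = c = d = 0
    for case in store:
        has_drug = any(
            drug.role in roles and drug.ingredient in exposures for drug in case.drugs
        )
        has_event = event in case_groups(case)
        if has_drug and has_event:
            a += 1
        elif has_drug:
            b += 1
        elif has_event:
            c += 1
        else:
            d += 1
    label = exposure if isinstance(exposure, str) else "+".join(sorted(exposures))
    return ContingencyCell(drug=label, event=event, a=a, b=b, c=c, d=d)


def evaluate_signal_criteria(
    result: SignalResult,
    cell: ContingencyCell,
    criteria: SignalCriteria = SignalCriteria(),
) -> SignalResult:
    """Apply the per-algorithm thresholds; NaN statistics fail their flag."""

    def _ok(v: float, threshold: float, strict: bool) -> bool:
        if math.isnan(v):
            return False
        return v > threshold if strict else v >= threshold

    enough = cell.a >= criteria.min_count
    flags = {
        "ROR": enough and _ok(result.ror_lo, criteria.ror_lo_gt, strict=True),
        "PRR": (
            enough
            and _ok(result.prr, criteria.prr_min, strict=False)
            and _ok(result.chi2, criteria.chi2_min, strict=False)
        ),
        "BCPNN": _ok(result.ic025, criteria.ic025_gt, strict=True),
        "MGPS": _ok(result.ebgm05, criteria.ebgm05_gt, strict=True),
    }
    result.flags = flags
    result.overall_signal = any(flags.values())
    return result


def compute_signal(
    cell: ContingencyCell,
    prior: eb.PriorParams | None = None,
    criteria: SignalCriteria = SignalCriteria(),
    ic_convention: str = "noren",
    eb05_method: str = "exact",
    haldane: bool = False,
) -> SignalResult:
    """All four algorithms for one cell.

    The Bayesian statistics require a fitted ``prior``; without one they
    stay NaN (and their flags false), which is convenient for quick
    frequentist-only scans.
    """
    res = SignalResult(drug=cell.drug, event=cell.event, a=cell.a)
    res.ror, res.ror_lo, res.ror_hi = compute_ror(cell, haldane=haldane)
    res.prr, res.chi2 = compute_prr_chi2(cell, haldane=haldane)
    if prior is not None:
        e = eb.expected_count(cell)
        if e > 0:
            shrink = eb.shrinkage_statistics(
                cell.a, e, prior, ic_convention=ic_convention, eb05_method=eb05_method
            )
            res.ebgm, res.ebgm05 = shrink.ebgm, shrink.ebgm05
            res.ic, res.ic025 = shrink.ic, shrink.ic025
    elif cell.n > 0:
        e = eb.expected_count(cell)
        if e > 0:
            res.ic, res.ic025 = eb.compute_ic(cell.a, e, convention="noren")
    return evaluate_signal_criteria(res, cell, criteria)


def _case_index(
    store: Sequence[CaseReport], roles: frozenset[str] | set[str]
) -> tuple[list[set[str]], list[set[str]]]:
    drug_sets = [
        {d.ingredient for d in case.drugs if d.role in roles and d.ingredient}
        for case in store
    ]
    event_sets = [case_groups(case) for case in store]
    return drug_sets, event_sets


def signal_grid(
    store: Sequence[CaseReport],
    roles: frozenset[str] | set[str] = frozenset({"PS"}),
    events: Iterable[str] | None = None,
) -> dict[tuple[str, str], ContingencyCell]:
    """Contingency cells for every (drug, event-group) pair in the store.

    The analysis universe (N of every cell) is the full deduplicated store;
    the drug universe is every normalized ingredient appearing under the
    role filter.
    """
    if not store:
        raise ValueError("case store is empty")
    drug_sets, event_sets = _case_index(store, roles)
    all_drugs = sorted(set().union(*drug_sets)) if drug_sets else []
    all_events = sorted(set(events)) if events is not None else sorted(
        set().union(*event_sets)
    )
    n = len(store)
    drug_totals = {g: 0 for g in all_drugs}
    event_totals = {ev: 0 for ev in all_events}
    pair_counts: dict[tuple[str, str], int] = {}
    for ds, es in zip(drug_sets, event_sets):
        for g in ds:
            drug_totals[g] = drug_totals.get(g, 0) + 1
        for ev in es:
            if ev in event_totals:
                event_totals[ev] += 1
        for g in ds:
            for ev in es:
                if ev in event_totals:
                    pair_counts[(g, ev)] = pair_counts.get((g, ev), 0) + 1
    grid: dict[tuple[str, str], ContingencyCell] = {}
    for g in all_drugs:
        for ev in all_events:
            a = pair_counts.get((g, ev), 0)
            b = drug_totals.get(g, 0) - a
            c = event_totals[ev] - a
            d = n - a - b - c
            grid[(g, ev)] = ContingencyCell(drug=g, event=ev, a=a, b=b, c=c, d=d)
    return grid


def fit_grid_prior(grid: Mapping[tuple[str, str], ContingencyCell],
                   truncated: bool = False) -> eb.PriorParams:
    """MGPS prior fitted over every cell of a drug×event grid (a=0 included)."""
    cells = [
        (cell.a, eb.expected_count(cell))
        for cell in grid.values()
        if eb.expected_count(cell) > 0
    ]
    return eb.fit_gamma_mixture_prior(cells, truncated=truncated)


def rank_drugs_for_event(
    store: Sequence[CaseReport],
    event: str,
    k: int = 30,
    roles: frozenset[str] | set[str] = frozenset({"PS"}),
    criteria: SignalCriteria = SignalCriteria(),
    ic_convention: str = "noren",
    eb05_method: str = "exact",
    prior: eb.PriorParams | None = None,
) -> pd.DataFrame:
    """Top-k drugs by case count for one event group, with all statistics.

    Ranks **all** normalized ingredients in the store (not only the target
    drugs), descending by ``a`` with alphabetical tie-break.  The MGPS
    prior is fitted once over the full drug×event grid unless supplied.
    Returns a DataFrame shaped like published top-30 signal tables.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    grid = signal_grid(store, roles=roles)
    if not any(key[1] == event for key in grid):
        raise ValueError(f"unknown event label {event!r}")
    if prior is None:
        prior = fit_grid_prior(grid)
    rows = []
    for (g, ev), cell in grid.items():
        if ev != event or cell.a == 0:
            continue
        res = compute_signal(cell, prior=prior, criteria=criteria,
                             ic_convention=ic_convention, eb05_method=eb05_method)
        rows.append(
            {
                "drug": g, "a": cell.a,
                "ror": res.ror, "ror_lo": res.ror_lo, "ror_hi": res.ror_hi,
                "prr": res.prr, "chi2": res.chi2,
                "ebgm": res.ebgm, "ebgm05": res.ebgm05,
                "ic": res.ic, "ic025": res.ic025,
                "flag_ror": res.flags["ROR"], "flag_prr": res.flags["PRR"],
                "flag_bcpnn": res.flags["BCPNN"], "flag_mgps": res.flags["MGPS"],
                "overall_signal": res.overall_signal,
            }
        )
    table = pd.DataFrame(rows)
    if table.empty:
        return table
    table = table.sort_values(["a", "drug"], ascending=[False, True], kind="mergesort")
    return table.head(k).reset_index(drop=True)
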