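"""Descriptive analyses over a deduplicated case store.

Beyond signal detection, pharmacovigilance studies report the shape of the
case series: demographic composition per drug, the annual reporting trend
(with a Spearman rank correlation against calendar year), time to onset
(TTO) from suspect-drug start to event onset, per-event-group mortality
rates, and a serious-vs-non-serious χ² association per event group.  Each
of those analyses lives here as one function over ``list[CaseReport]``.

Quartiles use linear interpolation between order statistics (the
convention where the median of {10,20,30,40,50} is 30 and the quartiles
are 20 and 40), stated in output metadata so published interquartile
ranges are reproducible.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .report_store import CaseReport
from .vocabulary import (
    NON_SERIOUS,
    SERIOUS,
    UNKNOWN,
    DrugDictionary,
    EventGroupMap,
    case_groups,
    classify_outcome_severity,
    select_suspect_exposures,
)

__all__ = [
    "TrendResult",
    "TTOSummary",
    "MortalityRow",
    "SeverityAssociation",
    "percentage",
    "spearman_trend",
    "annual_trend",
    "time_to_onset",
    "mortality_rates",
    "severity_association",
    "chi2_2x2",
    "demographic_table",
]


def percentage(numerator: float, denominator: float, ndigits: int = 2) -> float:
    """``100 · numerator / denominator`` rounded to ``ndigits``."""
    if denominator == 0:
        raise ZeroDivisionError("percentage denominator is zero")
    return round(100.0 * numerator / denominator, ndigits)


# ---------------------------------------------------------------------------
# annual trend


@dataclass
class TrendResult:
    counts: dict[int, int]
    r: float
    p_value: float


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, r_obs: float) -> float:
    """Two-sided exact permutation p for the Spearman correlation.

    Enumerates all n! orderings of the y-ranks (mid-ranks preserved) in
    chunks, so n = 10 stays within a few tens of MB.
    """
    n = len(rx)
    xc = rx - rx.mean()
    yc_norm = float(np.linalg.norm(ry - ry.mean()))
    denom = float(np.linalg.norm(xc)) * yc_norm
    if denom == 0:
        return 1.0
    hits = 0
    total = 0
    chunk: list[tuple[int, ...]] = []

    def flush(chunk: list[tuple[int, ...]]) -> int:
        perm = ry[np.array(chunk, dtype=np.int8)]
        r_perm = (perm - ry.mean()) @ xc / denom
        return int(np.sum(np.abs(r_perm) >= abs(r_obs) - 1e-12))

    for p in itertools.permutations(range(n)):
        chunk.append(p)
        total += 1
        if len(chunk) == 100_000:
            hits += flush(chunk)
            chunk = []
    if chunk:
        hits += flush(chunk)
    return hits / total


def spearman_trend(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 10
) -> tuple[float, float]:
    """Spearman correlation with mid-ranks for ties.

    The p-value is exact (full permutation enumeration) for n ≤
    ``exact_max_n`` and the t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length 1-d arrays with n >= 3")
    r, p_t = stats.spearmanr(x, y)
    r = float(r)
    if len(x) <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        return r, _exact_spearman_p(rx, ry, r)
    return r, float(p_t)


def annual_trend(
    store: Sequence[CaseReport],
    event_filter: Iterable[str] | None = None,
    group_map: EventGroupMap | None = None,
) -> TrendResult:
    """Per-year case counts and their Spearman correlation with the year.

    The reporting year is the year of the retained (latest) report
    version.  ``event_filter`` restricts to cases with ≥1 reaction in the
    given groups (default: any mapped event group).  Years inside the
    observed span without cases count as zero.  Fewer than 3 years of data
    is an error.
    """
    filt = set(event_filter) if event_filter is not None else None
    counts: dict[int, int] = {}
    for case in store:
        year = case.report_year
        if year is None:
            continue
        groups = case_groups(case)
        if filt is not None:
            if not (groups & filt):
                continue
        elif not groups:
            continue
        counts[year] = counts.get(year, 0) + 1
    if len(counts) < 1 or max(counts) - min(counts) + 1 < 3:
        raise ValueError("annual trend needs at least 3 calendar years of data")
    years = list(range(min(counts), max(counts) + 1))
    full = {y: counts.get(y, 0) for y in years}
    r, p = spearman_trend(years, [full[y] for y in years])
    return TrendResult(counts=full, r=r, p_value=p)


# ---------------------------------------------------------------------------
# time to onset


@dataclass
class TTOSummary:
    n_usable: int
    median_days: float = math.nan
    q1_days: float = math.nan
    q3_days: float = math.nan
    histogram: dict[int, int] = field(default_factory=dict)
    n_excluded_negative: int = 0
    n_excluded_undated: int = 0
    quartile_convention: str = "linear interpolation between order statistics"


def _summarize_intervals(
    intervals: list[int], n_neg: int, n_undated: int, bin_width: int
) -> TTOSummary:
    if not intervals:
        return TTOSummary(n_usable=0, n_excluded_negative=n_neg,
                          n_excluded_undated=n_undated)
    arr = np.asarray(intervals, dtype=float)
    q1, med, q3 = np.percentile(arr, [25, 50, 75], method="linear")
    hist: dict[int, int] = {}
    for v in intervals:
        start = (v // bin_width) * bin_width
        hist[start] = hist.get(start, 0) + 1
    return TTOSummary(
        n_usable=len(intervals),
        median_days=float(med),
        q1_days=float(q1),
        q3_days=float(q3),
        histogram=dict(sorted(hist.items())),
        n_excluded_negative=n_neg,
        n_excluded_undated=n_undated,
    )


def time_to_onset(
    store: Sequence[CaseReport],
    dictionary: DrugDictionary | None = None,
    event_filter: Iterable[str] | None = None,
    roles: frozenset[str] | set[str] = frozenset({"PS"}),
    bin_width: int = 30,
) -> dict[str, TTOSummary]:
    """Days from suspect-drug start to event onset, per drug and pooled.

    A usable interval needs a fully dated drug start and reaction onset;
    negative intervals and partially dated pairs are excluded and counted.
    The onset of a case is the earliest dated reaction in the event filter
    (default: any mapped event group); the pooled ``"ALL"`` summary uses
    the earliest start among the case's matched target-drug exposures.
    """
    dictionary = dictionary or DrugDictionary.default()
    filt = set(event_filter) if event_filter is not None else None
    per_drug: dict[str, list[int]] = {}
    neg: dict[str, int] = {}
    undated: dict[str, int] = {}

    def record(key: str, start, onset) -> None:
        if start is None or onset is None:
            undated[key] = undated.get(key, 0) + 1
            return
        days = (onset - start).days
        if days < 0:
            neg[key] = neg.get(key, 0) + 1
            return
        per_drug.setdefault(key, []).append(days)

    for case in store:
        exposures = select_suspect_exposures(case, dictionary, roles=roles)
        if not exposures:
            continue
        onsets = [
            r.onset_date
            for r in case.reactions
            if r.group is not None
            and (filt is None or r.group in filt)
            and r.onset_date is not None
        ]
        any_match = any(
            r.group is not None and (filt is None or r.group in filt)
            for r in case.reactions
        )
        if not any_match:
            continue
        onset = min(onsets) if onsets else None
        for ingredient, start in exposures:
            record(ingredient, start, onset)
        known_starts = [s for _, s in exposures if s is not None]
        record("ALL", min(known_starts) if known_starts else None, onset)

    return {
        key: _summarize_intervals(
            per_drug.get(key, []), neg.get(key, 0), undated.get(key, 0), bin_width
        )
        for key in sorted(set(per_drug) | set(neg) | set(undated))
    }


# ---------------------------------------------------------------------------
# mortality and severity


@dataclass(frozen=True)
class MortalityRow:
    deaths: int
    reports: int
    rate_pct: float


def mortality_rate(deaths: int, reports: int) -> MortalityRow:
    """Mortality rate of one event group: 100·deaths/reports, 2 dp."""
    if deaths > reports:
        raise ValueError("deaths cannot exceed reports")
    return MortalityRow(deaths=deaths, reports=reports,
                        rate_pct=percentage(deaths, reports))


def mortality_rates(
    store: Sequence[CaseReport], groups: Iterable[str] | None = None
) -> dict[str, MortalityRow]:
    """Per-event-group mortality: reported deaths / reported cases.

    ``reports`` counts distinct cases carrying the group; ``deaths`` those
    whose outcome set contains DE.  Groups with zero reports are omitted.
    """
    wanted = set(groups) if groups is not None else None
    deaths: dict[str, int] = {}
    reports: dict[str, int] = {}
    for case in store:
        fatal = "DE" in case.outcomes
        for g in case_groups(case):
            if wanted is not None and g not in wanted:
                continue
            reports[g] = reports.get(g, 0) + 1
            if fatal:
                deaths[g] = deaths.get(g, 0) + 1
    return {
        g: mortality_rate(deaths.get(g, 0), reports[g]) for g in sorted(reports)
    }


def chi2_2x2(
    table: Sequence[Sequence[float]], correction: str = "none"
) -> tuple[float, float, np.ndarray]:
    """Pearson χ² on a 2×2 table: statistic, p, expected counts.

    ``correction``: ``none`` (default), ``yates``, or ``fisher`` (p from
    Fisher's exact test; the statistic is then NaN).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError("table must be 2×2")
    if correction == "fisher":
        expected = stats.contingency.expected_freq(arr)
        _, p = stats.fisher_exact(arr)
        return math.nan, float(p), expected
    chi2, p, _, expected = stats.chi2_contingency(arr, correction=(correction == "yates"))
    return float(chi2), float(p), expected


@dataclass(frozen=True)
class SeverityAssociation:
    group: str
    serious: int
    non_serious: int
    chi2: float
    p_value: float
    correction: str


def severity_association(
    store: Sequence[CaseReport],
    group_map: EventGroupMap | None = None,
    method: str = "auto",
) -> dict[str, SeverityAssociation]:
    """Serious-vs-non-serious association per event group.

    The analysis universe is every case with ≥1 mapped event group and a
    known severity (death outcome = serious, other known outcome =
    non-serious; unknown excluded).  Each group is tested with a 2×2 of
    (in-group vs other) × (serious vs non-serious).  ``method`` is
    ``none``/``yates``/``fisher`` or ``auto`` (Pearson without correction,
    Fisher substituted when any expected cell < 5).  Groups with an empty
    margin are skipped.
    """
    gm = group_map or EventGroupMap.default()
    labelled: list[tuple[set[str], bool]] = []
    for case in store:
        groups = case_groups(case) & gm.nae_groups
        if not groups:
            continue
        severity = classify_outcome_severity(case.outcomes)
        if severity == UNKNOWN:
            continue
        labelled.append((groups, severity == SERIOUS))
    out: dict[str, SeverityAssociation] = {}
    all_groups = sorted(set().union(*(g for g, _ in labelled))) if labelled else []
    total_serious = sum(1 for _, s in labelled if s)
    total_non = len(labelled) - total_serious
    for g in all_groups:
        s_in = sum(1 for gs, s in labelled if s and g in gs)
        ns_in = sum(1 for gs, s in labelled if not s and g in gs)
        table = [[s_in, ns_in], [total_serious - s_in, total_non - ns_in]]
        if min(s_in + ns_in, sum(table[1]), s_in + table[1][0], ns_in + table[1][1]) == 0:
            continue
        use = method
        if method == "auto":
            _, _, expected = chi2_2x2(table, "none")
            use = "fisher" if (expected < 5).any() else "none"
        chi2, p, _ = chi2_2x2(table, use)
        if use == "fisher":  # report the Pearson statistic alongside Fisher's p
            chi2 = chi2_2x2(table, "none")[0]
        out[g] = SeverityAssociation(
            group=g, serious=s_in, non_serious=ns_in, chi2=chi2, p_value=p,
            correction=use,
        )
    return out


# ---------------------------------------------------------------------------
# demographics


_WEIGHT_BANDS = ("<50 kg", "50-100 kg", ">100 kg", "UNK")
#: one outcome per case, picked by clinical priority (death first)
_OUTCOME_PRIORITY = ("DE", "LT", "DS", "HO", "RI", "CA", "OT")


def _weight_band(weight: float | None) -> str:
    if weight is None:
        return "UNK"
    if weight < 50:
        return "<50 kg"
    if weight <= 100:
        return "50-100 kg"
    return ">100 kg"


def _primary_outcome(outcomes: set[str]) -> str:
    for code in _OUTCOME_PRIORITY:
        if code in outcomes:
            return code
    return "UNK"


_STRATUM_FUNCS: dict[str, Callable[[CaseReport], str]] = {
    "sex": lambda c: c.sex,
    "age_group": lambda c: c.age_group,
    "weight_band": lambda c: _weight_band(c.weight_kg),
    "reporter": lambda c: c.reporter,
    "outcome": lambda c: _primary_outcome(c.outcomes),
    "country": lambda c: c.country,
    "indication": lambda c: next(
        (d.indication_pt for d in c.drugs if d.indication_pt), "UNK"
    ),
    "year": lambda c: str(c.report_year or "UNK"),
}


def demographic_table(
    store: Sequence[CaseReport],
    dictionary: DrugDictionary | None = None,
    strata: Sequence[str] = ("sex", "age_group", "reporter", "outcome", "year"),
    roles: frozenset[str] | set[str] = frozenset({"PS"}),
) -> pd.DataFrame:
    """Per-drug counts and column percentages for categorical strata.

    One column of counts per target ingredient; a case exposed to two
    target drugs contributes to both columns.  Percentages are within each
    (stratum, drug) column and sum to 100 up to rounding.  Returns a tidy
    DataFrame with columns ``stratum, level, drug, count, pct``.
    """
    dictionary = dictionary or DrugDictionary.default()
    unknown = set(strata) - set(_STRATUM_FUNCS)
    if unknown:
        raise ValueError(f"unknown strata {sorted(unknown)}")
    counts: dict[tuple[str, str, str], int] = {}
    totals: dict[str, int] = {}
    for case in store:
        exposures = [ing for ing, _ in select_suspect_exposures(case, dictionary, roles)]
        for ing in exposures:
            totals[ing] = totals.get(ing, 0) + 1
            for stratum in strata:
                level = _STRATUM_FUNCS[stratum](case)
                key = (stratum, level, ing)
                counts[key] = counts.get(key, 0) + 1
    rows = [
        {
            "stratum": stratum,
            "level": level,
            "drug": ing,
            "count": n,
            "pct": percentage(n, totals[ing], 1),
        }
        for (stratum, level, ing), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["stratum", "level", "drug", "count", "pct"])
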