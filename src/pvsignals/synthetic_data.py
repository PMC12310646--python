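"""Ground-truthed synthetic spontaneous-report databases.

Real SRS extracts cannot be redistributed, so every upstream module is
exercised against simulated databases with known truth: a configurable
number of cases, each with one suspect drug drawn from a popularity
distribution, adverse events drawn from per-event background reporting
probabilities optionally multiplied by planted relative-risk signals,
demographics, drug start dates, log-normally distributed onset times,
outcome codes with event-specific death probabilities, and a fraction of
cases duplicated as stale earlier report versions.  The generator returns
both the deduplicated truth store and a :class:`GroundTruth` record (true
2×2 counts, planted relative risks, surviving version ids, onset
intervals), and can serialize the database in either raw-file dialect so
the full parse → dedup → annotate → signal pipeline is testable end to
end.

Everything is deterministic given the config seed; identical configs
produce byte-identical files.
"""

from __future__ import annotations

import csv
import datetime as _dt
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .report_store import CaseReport, DrugEntry, ReactionEntry
from .vocabulary import DrugDictionary

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_database",
    "write_faers_dialect",
    "write_jader_dialect",
]


def _default_drugs() -> dict[str, float]:
    # power-law popularity over seven target immunotherapies + common
    # co-reported background drugs
    names = [
        "nivolumab", "pembrolizumab", "atezolizumab", "ipilimumab",
        "durvalumab", "avelumab", "cemiplimab",
        "adalimumab", "rituximab", "levetiracetam", "methotrexate",
        "prednisolone", "carboplatin", "bevacizumab", "tacrolimus",
    ]
    weights = np.array([1.0 / (i + 1) for i in range(len(names))])
    weights /= weights.sum()
    return dict(zip(names, weights.tolist()))


def _default_events() -> dict[str, float]:
    # background per-case reporting probabilities; the neurological
    # immune-mediated PTs are rare against common general PTs
    return {
        "headache": 0.08,
        "nausea": 0.10,
        "fatigue": 0.08,
        "rash": 0.06,
        "diarrhoea": 0.06,
        "pyrexia": 0.05,
        "myasthenia gravis": 0.010,
        "myositis": 0.010,
        "encephalitis autoimmune": 0.006,
        "guillain-barre syndrome": 0.005,
        "meningitis aseptic": 0.004,
        "myelitis transverse": 0.003,
        "multiple sclerosis": 0.003,
        "chronic inflammatory demyelinating polyradiculoneuropathy": 0.002,
        "neuromyelitis optica spectrum disorder": 0.002,
    }


def _default_death_probs() -> dict[str, float]:
    # event-specific probabilities of a fatal outcome, shaped like
    # published NAE mortality rates (high for myasthenia/myopathy, low
    # for CIDP)
    return {
        "myasthenia gravis": 0.30,
        "myositis": 0.28,
        "encephalitis autoimmune": 0.20,
        "guillain-barre syndrome": 0.19,
        "meningitis aseptic": 0.04,
        "myelitis transverse": 0.15,
        "chronic inflammatory demyelinating polyradiculoneuropathy": 0.02,
        "neuromyelitis optica spectrum disorder": 0.10,
    }


@dataclass
class SimulationConfig:
    """Full specification of a synthetic spontaneous-report database."""

    n_cases: int = 20_000
    drugs: dict[str, float] = field(default_factory=_default_drugs)
    events: dict[str, float] = field(default_factory=_default_events)
    #: planted (drug, event-PT) -> relative-risk multipliers over background
    signal_pairs: dict[tuple[str, str], float] = field(
        default_factory=lambda: {("nivolumab", "myasthenia gravis"): 10.0}
    )
    duplicate_rate: float = 0.10
    death_prob_by_event: dict[str, float] = field(default_factory=_default_death_probs)
    default_death_prob: float = 0.03
    onset_mu_log: float = math.log(30.0)  # median 30 days
    onset_sigma_log: float = 0.8
    sex_probs: dict[str, float] = field(
        default_factory=lambda: {"M": 0.59, "F": 0.32, "UNK": 0.09}
    )
    age_group_probs: dict[str, float] = field(
        default_factory=lambda: {
            "<18": 0.016, "18-64": 0.261, "65-84": 0.485, ">85": 0.023, "UNK": 0.215,
        }
    )
    reporter_probs: dict[str, float] = field(
        default_factory=lambda: {
            "MD": 0.53, "HP": 0.19, "CN": 0.12, "PH": 0.07, "OT": 0.05, "UNK": 0.04,
        }
    )
    country_probs: dict[str, float] = field(
        default_factory=lambda: {
            "US": 0.30, "JP": 0.28, "FR": 0.09, "DE": 0.06, "GB": 0.05, "XX": 0.22,
        }
    )
    start_span: tuple[str, str] = ("20190101", "20240630")
    hospital_prob: float = 0.40  # HO outcome for surviving cases
    other_outcome_prob: float = 0.25  # OT outcome
    no_outcome_prob: float = 0.08  # report filed without outcome rows
    concomitant_rate: float = 0.0  # extra role-C drug rows
    same_group_extra_pt_rate: float = 0.0  # second PT of the same group
    brand_fraction: float = 0.0  # drug rows written under a brand synonym
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases <= 0:
            raise ValueError("n_cases must be positive")
        for p in list(self.events.values()) + [self.duplicate_rate]:
            if not (0 <= p <= 1):
                raise ValueError("probabilities must be in [0, 1]")
        for rr in self.signal_pairs.values():
            if rr <= 0:
                raise ValueError("relative risks must be positive")


@dataclass
class GroundTruth:
    """What the generator actually planted, for test harnesses."""

    n_cases: int
    cell_counts: dict[tuple[str, str], int]  # (drug, event PT) -> case count
    rr: dict[tuple[str, str], float]
    latest_version: dict[str, str]  # case_id -> surviving report id
    onset_days: dict[str, int]
    duplicated_cases: frozenset[str]


#: PTs of the same composite group as each default event, used by the
#: same-group multi-PT injection option
_SAME_GROUP_PARTNER = {
    "myasthenia gravis": "myasthenic syndrome",
    "myositis": "polymyositis",
    "encephalitis autoimmune": "autoimmune encephalopathy",
    "guillain-barre syndrome": "miller fisher syndrome",
    "meningitis aseptic": "meningitis noninfective",
    "myelitis transverse": "immune-mediated myelitis",
    "multiple sclerosis": "relapsing multiple sclerosis",
}

_AGE_RANGES = {"<18": (2, 17), "18-64": (18, 64), "65-84": (65, 84), ">85": (85, 95)}


def _choice(rng: np.random.Generator, probs: dict[str, float], size: int) -> list[str]:
    keys = list(probs)
    p = np.array([probs[k] for k in keys], dtype=float)
    p /= p.sum()
    idx = rng.choice(len(keys), size=size, p=p)
    return [keys[i] for i in idx]


def simulate_database(config: SimulationConfig) -> tuple[list[CaseReport], GroundTruth]:
    """Draw a full synthetic case store plus its ground truth.

    Per case: one suspect drug from the popularity weights; each event is
    included with probability ``p_e · rr(drug, e)`` capped at 1 (a warning
    count is unnecessary — the cap is deterministic); cases drawing no
    event are redrawn.  Onset days are log-normal; the event date is the
    drug start plus the onset; outcomes carry DE with the event-specific
    death probability.  A ``duplicate_rate`` fraction of cases will gain a
    stale earlier version when written to files.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_cases
    drug_names = list(cfg.drugs)
    drug_w = np.array([cfg.drugs[g] for g in drug_names], dtype=float)
    drug_w /= drug_w.sum()
    event_names = list(cfg.events)
    base_p = np.array([cfg.events[e] for e in event_names], dtype=float)

    # per-drug event probability matrix with planted signals, capped at 1
    prob = np.tile(base_p, (len(drug_names), 1))
    rr_map: dict[tuple[str, str], float] = {}
    for (g, ev) in [(g, ev) for g in drug_names for ev in event_names]:
        rr_map[(g, ev)] = 1.0
    for (g, ev), rr in cfg.signal_pairs.items():
        if g in drug_names and ev in event_names:
            prob[drug_names.index(g), event_names.index(ev)] = min(
                1.0, cfg.events[ev] * rr
            )
            rr_map[(g, ev)] = rr

    drug_idx = rng.choice(len(drug_names), size=n, p=drug_w)
    case_prob = prob[drug_idx]  # n × n_events
    mask = rng.random((n, len(event_names))) < case_prob
    for _ in range(100):
        empty = ~mask.any(axis=1)
        if not empty.any():
            break
        mask[empty] = rng.random((int(empty.sum()), len(event_names))) < case_prob[empty]
    empty = np.flatnonzero(~mask.any(axis=1))
    for i in empty:  # pathological configs: force one event by weight
        mask[i, rng.choice(len(event_names), p=case_prob[i] / case_prob[i].sum())] = True

    onset_days = np.rint(
        rng.lognormal(cfg.onset_mu_log, cfg.onset_sigma_log, size=n)
    ).astype(int)
    span_start = _dt.datetime.strptime(cfg.start_span[0], "%Y%m%d").date()
    span_end = _dt.datetime.strptime(cfg.start_span[1], "%Y%m%d").date()
    span_days = (span_end - span_start).days
    start_offsets = rng.integers(0, span_days + 1, size=n)

    sexes = _choice(rng, cfg.sex_probs, n)
    age_groups = _choice(rng, cfg.age_group_probs, n)
    reporters = _choice(rng, cfg.reporter_probs, n)
    countries = _choice(rng, cfg.country_probs, n)
    weight_known = rng.random(n) < 0.45
    weights = np.round(np.clip(rng.normal(75, 15, size=n), 35, 160), 1)
    dup_mask = rng.random(n) < cfg.duplicate_rate
    extra_pt_mask = rng.random(n) < cfg.same_group_extra_pt_rate
    concom_mask = rng.random(n) < cfg.concomitant_rate
    concom_idx = rng.choice(len(drug_names), size=n, p=drug_w)
    brand_mask = rng.random(n) < cfg.brand_fraction

    brand_of: dict[str, str] = {}
    if cfg.brand_fraction > 0:
        d = DrugDictionary.default()
        for ing, names in d.synonyms.items():
            brands = sorted(x for x in names if x.casefold() != ing)
            if brands:
                brand_of[ing] = brands[0].upper()

    cases: list[CaseReport] = []
    cell_counts: dict[tuple[str, str], int] = {}
    latest_version: dict[str, str] = {}
    onset_map: dict[str, int] = {}
    duplicated: set[str] = set()

    for i in range(n):
        case_id = str(100000 + i)
        drug = drug_names[drug_idx[i]]
        events_i = [event_names[j] for j in np.flatnonzero(mask[i])]
        for ev in events_i:
            cell_counts[(drug, ev)] = cell_counts.get((drug, ev), 0) + 1
        start = span_start + _dt.timedelta(days=int(start_offsets[i]))
        onset = int(onset_days[i])
        event_date = start + _dt.timedelta(days=onset)
        receipt = event_date + _dt.timedelta(days=7)
        n_versions = 2 if dup_mask[i] else 1
        pid = f"{case_id}{n_versions}"
        if dup_mask[i]:
            duplicated.add(case_id)

        death_draws = rng.random(len(events_i))
        fatal = any(
            u < cfg.death_prob_by_event.get(ev, cfg.default_death_prob)
            for u, ev in zip(death_draws, events_i)
        )
        outcomes: set[str] = set()
        if fatal:
            outcomes.add("DE")
        else:
            u = rng.random()
            if u < cfg.no_outcome_prob:
                pass
            elif u < cfg.no_outcome_prob + cfg.hospital_prob:
                outcomes.add("HO")
            elif u < cfg.no_outcome_prob + cfg.hospital_prob + cfg.other_outcome_prob:
                outcomes.add("OT")
            else:
                outcomes.add("LT")

        age_group = age_groups[i]
        if age_group == "UNK":
            age_years: float | None = None
        else:
            lo, hi = _AGE_RANGES[age_group]
            age_years = float(rng.integers(lo, hi + 1))

        raw_name = brand_of.get(drug, drug) if brand_mask[i] else drug
        drugs = [DrugEntry(raw_name=raw_name, role="PS", start_date=start,
                           indication_pt="malignant neoplasm")]
        if concom_mask[i]:
            co = drug_names[concom_idx[i]]
            if co != drug:
                drugs.append(DrugEntry(raw_name=co, role="C", start_date=start))

        pts = list(events_i)
        if extra_pt_mask[i]:
            for ev in events_i:
                partner = _SAME_GROUP_PARTNER.get(ev)
                if partner and partner not in pts:
                    pts.append(partner)
                    break
        reactions = [ReactionEntry(pt=pt, onset_date=event_date) for pt in pts]

        receipt_int = int(receipt.strftime("%Y%m%d"))
        cases.append(
            CaseReport(
                case_id=case_id,
                version_key=(receipt_int, int(pid)),
                sex=sexes[i],
                age_years=age_years,
                age_group=age_group,
                weight_kg=float(weights[i]) if weight_known[i] else None,
                reporter=reporters[i],
                country=countries[i],
                event_date=event_date,
                drugs=drugs,
                reactions=reactions,
                outcomes=outcomes,
            )
        )
        latest_version[case_id] = pid
        onset_map[case_id] = onset

    truth = GroundTruth(
        n_cases=n,
        cell_counts=cell_counts,
        rr=rr_map,
        latest_version=latest_version,
        onset_days=onset_map,
        duplicated_cases=frozenset(duplicated),
    )
    return cases, truth


# ---------------------------------------------------------------------------
# dialect writers


def _ds(d: _dt.date | None) -> str:
    return d.strftime("%Y%m%d") if d else ""


def _versions(case: CaseReport, truth: GroundTruth):
    """Yield (pid, seq, receipt, is_latest) for every report version.

    Earlier duplicate versions are stale: 30 days older, lower sequence,
    and written with degraded content (unknown sex, no outcomes) so that a
    wrong dedup choice is detectable field-by-field.
    """
    receipt_int, _ = case.version_key
    latest_pid = truth.latest_version[case.case_id]
    if case.case_id in truth.duplicated_cases:
        receipt = _dt.datetime.strptime(str(receipt_int), "%Y%m%d").date()
        early = (receipt - _dt.timedelta(days=30)).strftime("%Y%m%d")
        yield f"{case.case_id}1", 1, early, False
    yield latest_pid, int(latest_pid[-1]), str(receipt_int), True


def write_faers_dialect(
    store: list[CaseReport],
    truth: GroundTruth,
    out_dir: str | Path,
    quarter_label: str = "2024Q1",
) -> dict[str, Path]:
    """Write DEMO/DRUG/REAC/OUTC/INDI ``$``-delimited files.

    Round-tripping through ``parse_faers_quarter`` + ``deduplicate_cases``
    reconstructs the store exactly (content fields; version keys are
    re-derived from the files).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    label = quarter_label.replace("Q", "q")
    paths = {t: out / f"{t.lower()}{label}.txt" for t in ("DEMO", "DRUG", "REAC", "OUTC", "INDI")}

    def rows_of(case: CaseReport):
        for pid, _, receipt, latest in _versions(case, truth):
            yield pid, receipt, latest

    with paths["DEMO"].open("w", newline="") as demo, \
            paths["DRUG"].open("w", newline="") as drug, \
            paths["REAC"].open("w", newline="") as reac, \
            paths["OUTC"].open("w", newline="") as outc, \
            paths["INDI"].open("w", newline="") as indi:
        demo.write("primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$wt$wt_cod$"
                   "occp_cod$reporter_country$occr_country\n")
        drug.write("primaryid$caseid$drug_seq$role_cod$drugname$start_dt\n")
        reac.write("primaryid$caseid$pt\n")
        outc.write("primaryid$caseid$outc_cod\n")
        indi.write("primaryid$caseid$indi_drug_seq$indi_pt\n")
        for case in store:
            for pid, receipt, latest in rows_of(case):
                sex = case.sex if latest else "UNK"
                age = "" if case.age_years is None else str(int(case.age_years))
                wt = "" if case.weight_kg is None else f"{case.weight_kg:.1f}"
                demo.write(
                    f"{pid}${case.case_id}${receipt}${_ds(case.event_date)}${age}$"
                    f"{'YR' if age else ''}${'' if sex == 'UNK' else sex}${wt}$"
                    f"{'KG' if wt else ''}${'' if case.reporter == 'UNK' else case.reporter}$"
                    f"{'' if case.country == 'UNK' else case.country}$\n"
                )
                for seq, d in enumerate(case.drugs, start=1):
                    drug.write(
                        f"{pid}${case.case_id}${seq}${d.role}${d.raw_name}$"
                        f"{_ds(d.start_date)}\n"
                    )
                    if d.indication_pt:
                        indi.write(f"{pid}${case.case_id}${seq}${d.indication_pt}\n")
                for r in case.reactions:
                    reac.write(f"{pid}${case.case_id}${r.pt}\n")
                if latest:
                    for code in sorted(case.outcomes):
                        outc.write(f"{pid}${case.case_id}${code}\n")
    return {k.lower(): v for k, v in paths.items()}


def write_jader_dialect(
    store: list[CaseReport],
    truth: GroundTruth,
    out_dir: str | Path,
    encoding: str = "utf-8",
) -> dict[str, Path]:
    """Write comma-separated demo/drug/reac files in the JADER dialect.

    No outcome table exists in this dialect, so severities downstream are
    UNKNOWN.  ``encoding`` switches the byte encoding only; the content is
    identical.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {t: out / f"{t}.csv" for t in ("demo", "drug", "reac")}
    with paths["demo"].open("w", newline="", encoding=encoding) as demo, \
            paths["drug"].open("w", newline="", encoding=encoding) as drug, \
            paths["reac"].open("w", newline="", encoding=encoding) as reac:
        wd = csv.writer(demo, lineterminator="\n")
        wg = csv.writer(drug, lineterminator="\n")
        wr = csv.writer(reac, lineterminator="\n")
        wd.writerow(["case_id", "seq_no", "sex", "age", "weight", "reporter",
                     "receipt_date", "event_date", "country"])
        wg.writerow(["case_id", "seq_no", "role", "drug_name", "start_date"])
        wr.writerow(["case_id", "seq_no", "pt", "onset_date"])
        for case in store:
            for pid, seq, receipt, latest in _versions(case, truth):
                sex = case.sex if latest else "UNK"
                wd.writerow([
                    case.case_id, seq, "" if sex == "UNK" else sex,
                    "" if case.age_years is None else int(case.age_years),
                    "" if case.weight_kg is None else f"{case.weight_kg:.1f}",
                    "" if case.reporter == "UNK" else case.reporter,
                    receipt, _ds(case.event_date),
                    "" if case.country == "UNK" else case.country,
                ])
                for d in case.drugs:
                    wg.writerow([case.case_id, seq, d.role, d.raw_name,
                                 _ds(d.start_date)])
                for r in case.reactions:
                    wr.writerow([case.case_id, seq, r.pt, _ds(r.onset_date)])
    return {k: v for k, v in paths.items()}
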