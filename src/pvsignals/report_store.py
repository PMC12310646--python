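"""Parse spontaneous adverse-event report tables into a unified case store.

Spontaneous reporting systems (SRS) such as the FDA Adverse Event Reporting
System (FAERS) and the Japanese Adverse Drug Event Report database (JADER)
distribute their data as flat per-quarter tables: one demographic row per
report version, plus child tables of drugs, coded reactions (MedDRA
preferred terms), and patient outcomes.  A single *case* may appear several
times as successive report versions; pharmacovigilance analyses keep only
the latest version of each case.

This module reads both dialects (FAERS ``$``-delimited ASCII, JADER CSV),
selects the latest version per case, joins the child tables, and produces a
list of :class:`CaseReport` objects — the in-memory container every
downstream analysis consumes.  A case store can be round-tripped through a
directory of TSV files (:func:`write_store` / :func:`read_store`).
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

logger = logging.getLogger(__name__)

SEX_CODES = frozenset({"F", "M"})
ROLE_CODES = frozenset({"PS", "SS", "C", "I"})
OUTCOME_CODES = frozenset({"DE", "LT", "HO", "DS", "CA", "RI", "OT"})
REPORTER_CODES = frozenset({"HP", "MD", "PH", "OT", "CN"})
AGE_GROUPS = ("<18", "18-64", "65-84", ">85", "UNK")

#: multiplicative factors converting FAERS age units to years
_AGE_UNIT_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 7.0 / 365.25,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8760.0,
}

# Column-name aliases across FAERS eras (pre-2012 Legacy AERS used e.g.
# "isr"/"case") and for the JADER dialect.  Canonical name -> accepted
# lowercase header names, first match wins.
DEFAULT_FAERS_ALIASES: dict[str, tuple[str, ...]] = {
    "primaryid": ("primaryid", "isr"),
    "caseid": ("caseid", "case"),
    "fda_dt": ("fda_dt", "init_fda_dt", "rept_dt"),
    "event_dt": ("event_dt",),
    "age": ("age",),
    "age_cod": ("age_cod",),
    "sex": ("sex", "gndr_cod"),
    "wt": ("wt",),
    "wt_cod": ("wt_cod",),
    "occp_cod": ("occp_cod",),
    "reporter_country": ("reporter_country",),
    "occr_country": ("occr_country",),
    "role_cod": ("role_cod",),
    "drug_seq": ("drug_seq", "drugseq"),
    "drugname": ("drugname",),
    "start_dt": ("start_dt",),
    "pt": ("pt",),
    "outc_cod": ("outc_cod", "outc_code"),
    "indi_pt": ("indi_pt",),
    "indi_drug_seq": ("indi_drug_seq",),
}

DEFAULT_JADER_ALIASES: dict[str, tuple[str, ...]] = {
    "case_id": ("case_id", "識別番号"),
    "seq_no": ("seq_no", "報告回数"),
    "sex": ("sex", "性別"),
    "age": ("age", "年齢"),
    "weight": ("weight", "体重"),
    "reporter": ("reporter", "報告者の資格"),
    "receipt_date": ("receipt_date", "報告年度"),
    "event_date": ("event_date",),
    "country": ("country", "報告国"),
    "role": ("role", "医薬品の関与"),
    "drug_name": ("drug_name", "医薬品名"),
    "start_date": ("start_date", "投与開始日"),
    "pt": ("pt", "有害事象"),
    "onset_date": ("onset_date", "発現日"),
}


# ---------------------------------------------------------------------------
# domain types


@dataclass
class DrugEntry:
    """One drug row of a report: verbatim name, role code, optional dates."""

    raw_name: str
    role: str = "PS"
    ingredient: str | None = None  # filled by vocabulary.annotate_store
    start_date: _dt.date | None = None
    indication_pt: str | None = None

    def __post_init__(self) -> None:
        if self.role not in ROLE_CODES:
            raise ValueError(f"unknown drug role code {self.role!r}")


@dataclass
class ReactionEntry:
    """One coded reaction: MedDRA preferred term, optional onset date."""

    pt: str
    group: str | None = None  # composite event label, filled by vocabulary
    onset_date: _dt.date | None = None

    def __post_init__(self) -> None:
        if not self.pt:
            raise ValueError("reaction PT must be non-empty")


@dataclass
class CaseReport:
    """One deduplicated safety report.

    ``version_key`` is ``(receipt-date as YYYYMMDD int, report sequence)``;
    the deduplicator keeps the case version with the maximal key.  Unknown
    categorical fields carry the string ``"UNK"``; unknown numerics are
    ``None``.
    """

    case_id: str
    version_key: tuple[int, int] = (0, 0)
    sex: str = "UNK"
    age_years: float | None = None
    age_group: str = "UNK"
    weight_kg: float | None = None
    reporter: str = "UNK"
    country: str = "UNK"
    event_date: _dt.date | None = None
    drugs: list[DrugEntry] = field(default_factory=list)
    reactions: list[ReactionEntry] = field(default_factory=list)
    outcomes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.case_id:
            raise ValueError("case_id must be non-empty")
        bad = self.outcomes - OUTCOME_CODES
        if bad:
            raise ValueError(f"unknown outcome codes {sorted(bad)}")

    @property
    def report_year(self) -> int | None:
        """Calendar year of the retained (latest) report version."""
        if self.version_key[0] >= 10000:
            return self.version_key[0] // 10000
        return None


@dataclass
class RawTableSet:
    """Raw rows of one parsed quarter/export, keyed by lowercase column."""

    source: str  # "FAERS" | "JADER"
    demo_rows: list[dict[str, str]] = field(default_factory=list)
    drug_rows: list[dict[str, str]] = field(default_factory=list)
    reac_rows: list[dict[str, str]] = field(default_factory=list)
    outc_rows: list[dict[str, str]] = field(default_factory=list)
    indi_rows: list[dict[str, str]] = field(default_factory=list)
    quarter_label: str = ""
    n_skipped: dict[str, int] = field(default_factory=dict)


@dataclass
class DedupStats:
    """Bookkeeping from :func:`deduplicate_cases`."""

    n_demo_rows: int = 0
    n_cases: int = 0
    n_versions_dropped: int = 0
    n_orphan_rows: int = 0
    n_tie_breaks_by_order: int = 0


# ---------------------------------------------------------------------------
# date / numeric helpers


def parse_partial_date(raw: str | None) -> tuple[int, _dt.date | None]:
    """Parse a possibly partial numeric date.

    Returns ``(sort_key, date)``.  Full ``YYYYMMDD`` strings yield a real
    :class:`datetime.date`; partial ``YYYYMM``/``YYYY`` strings are
    zero-padded into the sort key only (day precision would be fabricated),
    with ``date`` left as ``None``.  Unparseable input gives ``(0, None)``.
    """
    s = (raw or "").strip()
    if not s.isdigit():
        return 0, None
    if len(s) == 8:
        try:
            return int(s), _dt.datetime.strptime(s, "%Y%m%d").date()
        except ValueError:
            return int(s), None
    if len(s) == 6:
        return int(s) * 100, None
    if len(s) == 4:
        return int(s) * 10000, None
    return 0, None


def _parse_float(raw: str | None) -> float | None:
    try:
        v = float((raw or "").strip())
    except ValueError:
        return None
    return v if v >= 0 else None


def age_to_years(age: str | None, unit: str | None) -> float | None:
    """Convert a FAERS age + unit code to years; unknown unit -> None."""
    v = _parse_float(age)
    if v is None:
        return None
    factor = _AGE_UNIT_TO_YEARS.get((unit or "YR").strip().upper() or "YR")
    if factor is None:
        return None
    return v * factor


def age_group_of(age_years: float | None) -> str:
    """Band an age in years into the four analysis groups (or UNK)."""
    if age_years is None:
        return "UNK"
    if age_years < 18:
        return "<18"
    if age_years < 65:
        return "18-64"
    if age_years < 85:
        return "65-84"
    return ">85"


def _weight_kg(wt: str | None, unit: str | None) -> float | None:
    v = _parse_float(wt)
    if v is None:
        return None
    u = (unit or "KG").strip().upper() or "KG"
    if u in ("KG", "KGS"):
        return v
    if u in ("LBS", "LB"):
        return v * 0.45359237
    return None


class _Aliases:
    def __init__(self, table: Mapping[str, Sequence[str]]):
        self.table = table

    def get(self, row: Mapping[str, str], canonical: str, default: str = "") -> str:
        for name in self.table.get(canonical, (canonical,)):
            if name in row:
                return row[name]
        return default


# ---------------------------------------------------------------------------
# parsing


def _read_delimited(
    path: Path, delimiter: str, table: str, encoding: str = "utf-8"
) -> tuple[list[dict[str, str]], int]:
    """Read a header-ed delimited text file into lowercase-keyed row dicts.

    Rows whose field count differs from the header are skipped and counted.
    FAERS ASCII files never quote fields, so a plain split suffices there;
    JADER CSV goes through :mod:`csv` for quoting support.
    """
    try:
        raw = path.read_bytes()
    except FileNotFoundError:
        raise FileNotFoundError(f"required {table} table missing: {path}") from None
    try:
        text = raw.decode(encoding)
    except UnicodeDecodeError as e:
        raise ValueError(
            f"{table} table {path} is not valid {encoding} "
            f"(undecodable byte at offset {e.start})"
        ) from None

    if delimiter == ",":
        reader = csv.reader(text.splitlines())
        lines = [row for row in reader]
    else:
        lines = [line.split(delimiter) for line in text.splitlines() if line != ""]
    if not lines:
        logger.warning("table %s (%s) is empty", table, path)
        return [], 0

    header = [h.strip().lower() for h in lines[0]]
    rows: list[dict[str, str]] = []
    skipped = 0
    for fields_ in lines[1:]:
        if len(fields_) != len(header):
            skipped += 1
            continue
        rows.append({h: v.strip() for h, v in zip(header, fields_)})
    if skipped:
        logger.warning("table %s: skipped %d malformed row(s)", table, skipped)
    return rows, skipped


def parse_faers_quarter(
    paths: Mapping[str, str | Path], quarter_label: str = ""
) -> RawTableSet:
    """Parse one FAERS quarter of ``$``-delimited ASCII tables.

    ``paths`` maps table names (case-insensitive: ``DEMO``, ``DRUG``,
    ``REAC``, and optionally ``OUTC``, ``INDI``) to file paths.  DEMO, DRUG
    and REAC are required.  Malformed rows (wrong field count) are skipped;
    skip counts are reported in :attr:`RawTableSet.n_skipped`.
    """
    norm = {k.strip().lower(): Path(v) for k, v in paths.items()}
    for required in ("demo", "drug", "reac"):
        if required not in norm:
            raise FileNotFoundError(f"required {required.upper()} table not supplied")
    out = RawTableSet(source="FAERS", quarter_label=quarter_label)
    for table, attr in (
        ("demo", "demo_rows"),
        ("drug", "drug_rows"),
        ("reac", "reac_rows"),
        ("outc", "outc_rows"),
        ("indi", "indi_rows"),
    ):
        if table not in norm:
            continue
        rows, skipped = _read_delimited(norm[table], "$", table.upper())
        setattr(out, attr, rows)
        out.n_skipped[table] = skipped
    return out


def parse_jader_tables(
    paths: Mapping[str, str | Path], encoding: str = "utf-8"
) -> RawTableSet:
    """Parse a JADER-dialect export (comma-separated demo/drug/reac).

    ``encoding`` is configurable; pass ``"cp932"`` for Shift-JIS-style
    exports.  Undecodable bytes raise :class:`ValueError` with the byte
    offset.  The outcome table does not exist in this dialect, so
    ``outc_rows`` is always empty and downstream severity is UNKNOWN.
    """
    norm = {k.strip().lower(): Path(v) for k, v in paths.items()}
    for required in ("demo", "drug", "reac"):
        if required not in norm:
            raise FileNotFoundError(f"required {required.upper()} table not supplied")
    out = RawTableSet(source="JADER")
    for table, attr in (("demo", "demo_rows"), ("drug", "drug_rows"), ("reac", "reac_rows")):
        rows, skipped = _read_delimited(norm[table], ",", table.upper(), encoding)
        setattr(out, attr, rows)
        out.n_skipped[table] = skipped
    return out


# ---------------------------------------------------------------------------
# deduplication + join


def _norm_sex(raw: str) -> str:
    s = raw.strip().upper()
    return s if s in SEX_CODES else "UNK"


def _norm_reporter(raw: str) -> str:
    s = raw.strip().upper()
    return s if s in REPORTER_CODES else "UNK"


def _int_or_zero(raw: str) -> int:
    s = raw.strip()
    return int(s) if s.isdigit() else 0


def _faers_cases(raws: Sequence[RawTableSet], al: _Aliases, stats: DedupStats) -> list[CaseReport]:
    # index all demo versions by caseid, children by primaryid
    versions: dict[str, tuple[tuple[int, int], dict[str, str], str]] = {}
    demo_ids: set[str] = set()
    for raw in raws:
        for row in raw.demo_rows:
            pid = al.get(row, "primaryid").strip()
            cid = al.get(row, "caseid").strip() or pid
            if not pid and not cid:
                continue
            stats.n_demo_rows += 1
            demo_ids.add(pid)
            key = (parse_partial_date(al.get(row, "fda_dt"))[0], _int_or_zero(pid))
            prev = versions.get(cid)
            if prev is None:
                versions[cid] = (key, row, pid)
            else:
                if key > prev[0]:
                    versions[cid] = (key, row, pid)
                elif key == prev[0]:
                    stats.n_tie_breaks_by_order += 1
                    versions[cid] = (key, row, pid)  # last-read wins, logged
                    logger.debug("case %s: version tie broken by read order", cid)
                stats.n_versions_dropped += 1

    by_pid_drug: dict[str, list[dict[str, str]]] = {}
    by_pid_reac: dict[str, list[dict[str, str]]] = {}
    by_pid_outc: dict[str, list[dict[str, str]]] = {}
    by_pid_indi: dict[str, list[dict[str, str]]] = {}
    for raw in raws:
        for rows, index in (
            (raw.drug_rows, by_pid_drug),
            (raw.reac_rows, by_pid_reac),
            (raw.outc_rows, by_pid_outc),
            (raw.indi_rows, by_pid_indi),
        ):
            for row in rows:
                pid = al.get(row, "primaryid").strip()
                if pid not in demo_ids:
                    stats.n_orphan_rows += 1
                    continue
                index.setdefault(pid, []).append(row)

    cases: list[CaseReport] = []
    for cid in sorted(versions):
        key, demo, pid = versions[cid]
        event_date = parse_partial_date(al.get(demo, "event_dt"))[1]
        age_years = age_to_years(al.get(demo, "age"), al.get(demo, "age_cod"))
        country = al.get(demo, "reporter_country").strip() or al.get(
            demo, "occr_country"
        ).strip() or "UNK"

        indi_by_seq: dict[str, str] = {}
        for row in by_pid_indi.get(pid, ()):
            seq = al.get(row, "indi_drug_seq").strip()
            pt = al.get(row, "indi_pt").strip()
            if pt:
                indi_by_seq[seq] = pt

        drugs = []
        for row in by_pid_drug.get(pid, ()):
            name = al.get(row, "drugname").strip()
            role = al.get(row, "role_cod").strip().upper()
            if not name or role not in ROLE_CODES:
                continue
            seq = al.get(row, "drug_seq").strip()
            drugs.append(
                DrugEntry(
                    raw_name=name,
                    role=role,
                    start_date=parse_partial_date(al.get(row, "start_dt"))[1],
                    indication_pt=indi_by_seq.get(seq) or None,
                )
            )
        reactions = [
            ReactionEntry(pt=pt, onset_date=event_date)
            for row in by_pid_reac.get(pid, ())
            if (pt := al.get(row, "pt").strip())
        ]
        outcomes = {
            code
            for row in by_pid_outc.get(pid, ())
            if (code := al.get(row, "outc_cod").strip().upper()) in OUTCOME_CODES
        }
        cases.append(
            CaseReport(
                case_id=cid,
                version_key=key,
                sex=_norm_sex(al.get(demo, "sex")),
                age_years=age_years,
                age_group=age_group_of(age_years),
                weight_kg=_weight_kg(al.get(demo, "wt"), al.get(demo, "wt_cod")),
                reporter=_norm_reporter(al.get(demo, "occp_cod")),
                country=country,
                event_date=event_date,
                drugs=drugs,
                reactions=reactions,
                outcomes=outcomes,
            )
        )
    stats.n_cases = len(cases)
    return cases


def _jader_cases(raws: Sequence[RawTableSet], al: _Aliases, stats: DedupStats) -> list[CaseReport]:
    versions: dict[str, tuple[tuple[int, int], dict[str, str]]] = {}
    case_ids: set[str] = set()
    for raw in raws:
        for row in raw.demo_rows:
            cid = al.get(row, "case_id").strip()
            if not cid:
                continue
            stats.n_demo_rows += 1
            case_ids.add(cid)
            key = (
                parse_partial_date(al.get(row, "receipt_date"))[0],
                _int_or_zero(al.get(row, "seq_no")),
            )
            prev = versions.get(cid)
            if prev is None or key > prev[0]:
                if prev is not None:
                    stats.n_versions_dropped += 1
                versions[cid] = (key, row)
            else:
                if key == prev[0]:
                    stats.n_tie_breaks_by_order += 1
                    versions[cid] = (key, row)
                stats.n_versions_dropped += 1

    by_cid_drug: dict[str, list[dict[str, str]]] = {}
    by_cid_reac: dict[str, list[dict[str, str]]] = {}
    for raw in raws:
        for rows, index in ((raw.drug_rows, by_cid_drug), (raw.reac_rows, by_cid_reac)):
            for row in rows:
                cid = al.get(row, "case_id").strip()
                if cid not in case_ids:
                    stats.n_orphan_rows += 1
                    continue
                index.setdefault(cid, []).append(row)

    cases: list[CaseReport] = []
    for cid in sorted(versions):
        key, demo = versions[cid]
        seq = al.get(demo, "seq_no").strip()
        event_date = parse_partial_date(al.get(demo, "event_date"))[1]
        age_years = _parse_float(al.get(demo, "age"))

        def _belongs(row: dict[str, str]) -> bool:
            row_seq = al.get(row, "seq_no").strip()
            return (not row_seq) or row_seq == seq

        drugs = []
        for row in by_cid_drug.get(cid, ()):
            if not _belongs(row):
                continue
            name = al.get(row, "drug_name").strip()
            role = al.get(row, "role").strip().upper()
            if not name or role not in ROLE_CODES:
                continue
            drugs.append(
                DrugEntry(
                    raw_name=name,
                    role=role,
                    start_date=parse_partial_date(al.get(row, "start_date"))[1],
                )
            )
        reactions = []
        for row in by_cid_reac.get(cid, ()):
            if not _belongs(row):
                continue
            pt = al.get(row, "pt").strip()
            if not pt:
                continue
            onset = parse_partial_date(al.get(row, "onset_date"))[1] or event_date
            reactions.append(ReactionEntry(pt=pt, onset_date=onset))
        cases.append(
            CaseReport(
                case_id=cid,
                version_key=key,
                sex=_norm_sex(al.get(demo, "sex")),
                age_years=age_years,
                age_group=age_group_of(age_years),
                weight_kg=_parse_float(al.get(demo, "weight")),
                reporter=_norm_reporter(al.get(demo, "reporter")),
                country=al.get(demo, "country").strip() or "UNK",
                event_date=event_date,
                drugs=drugs,
                reactions=reactions,
                outcomes=set(),  # JADER dialect ships no outcome table
            )
        )
    stats.n_cases = len(cases)
    return cases


def deduplicate_cases(
    *raws: RawTableSet,
    aliases: Mapping[str, Sequence[str]] | None = None,
    stats: DedupStats | None = None,
) -> list[CaseReport]:
    """Collapse report versions to one :class:`CaseReport` per case.

    For each case identifier, the version with the maximal
    ``(receipt date, report sequence)`` key survives; exact ties fall back
    to last-read order (logged and counted).  Child rows (drugs, reactions,
    outcomes, indications) are joined to the surviving version; child rows
    whose report id has no demographic row are orphans, dropped and counted.
    Cases are returned sorted by case id.  The operation is idempotent.
    """
    if not raws:
        raise ValueError("at least one RawTableSet required")
    sources = {raw.source for raw in raws}
    if len(sources) != 1:
        raise ValueError(f"cannot mix sources {sorted(sources)} in one dedup pass")
    source = sources.pop()
    stats = stats if stats is not None else DedupStats()
    if source == "FAERS":
        al = _Aliases(aliases or DEFAULT_FAERS_ALIASES)
        return _faers_cases(raws, al, stats)
    al = _Aliases(aliases or DEFAULT_JADER_ALIASES)
    return _jader_cases(raws, al, stats)


# ---------------------------------------------------------------------------
# store (de)serialization


def _date_str(d: _dt.date | None) -> str:
    return d.strftime("%Y%m%d") if d else ""


def _opt_float(v: float | None) -> str:
    return "" if v is None else repr(v)


def write_store(
    cases: Iterable[CaseReport],
    out_dir: str | Path,
    source: str = "",
    manifest_extra: Mapping[str, object] | None = None,
) -> Path:
    """Serialize a case store to a directory of TSVs plus a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases = list(cases)

    def _w(name: str, header: list[str], rows: Iterable[list[str]]) -> None:
        with (out / name).open("w", newline="") as fh:
            writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
            writer.writerow(header)
            writer.writerows(rows)

    _w(
        "cases.tsv",
        ["case_id", "receipt", "seq", "sex", "age_years", "age_group",
         "weight_kg", "reporter", "country", "event_date"],
        (
            [c.case_id, str(c.version_key[0]), str(c.version_key[1]), c.sex,
             _opt_float(c.age_years), c.age_group, _opt_float(c.weight_kg),
             c.reporter, c.country, _date_str(c.event_date)]
            for c in cases
        ),
    )
    _w(
        "drugs.tsv",
        ["case_id", "raw_name", "ingredient", "role", "start_date", "indication_pt"],
        (
            [c.case_id, d.raw_name, d.ingredient or "", d.role,
             _date_str(d.start_date), d.indication_pt or ""]
            for c in cases
            for d in c.drugs
        ),
    )
    _w(
        "reactions.tsv",
        ["case_id", "pt", "group", "onset_date"],
        (
            [c.case_id, r.pt, r.group or "", _date_str(r.onset_date)]
            for c in cases
            for r in c.reactions
        ),
    )
    _w(
        "outcomes.tsv",
        ["case_id", "code"],
        ([c.case_id, code] for c in cases for code in sorted(c.outcomes)),
    )
    manifest = {"source": source, "n_cases": len(cases)}
    if manifest_extra:
        manifest.update(manifest_extra)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def read_store(in_dir: str | Path) -> list[CaseReport]:
    """Load a case store written by :func:`write_store`."""
    src = Path(in_dir)

    def _rows(name: str) -> list[dict[str, str]]:
        with (src / name).open(newline="") as fh:
            return list(csv.DictReader(fh, delimiter="\t"))

    def _date(s: str) -> _dt.date | None:
        return parse_partial_date(s)[1] if s else None

    cases: dict[str, CaseReport] = {}
    for row in _rows("cases.tsv"):
        cases[row["case_id"]] = CaseReport(
            case_id=row["case_id"],
            version_key=(int(row["receipt"]), int(row["seq"])),
            sex=row["sex"],
            age_years=float(row["age_years"]) if row["age_years"] else None,
            age_group=row["age_group"],
            weight_kg=float(row["weight_kg"]) if row["weight_kg"] else None,
            reporter=row["reporter"],
            country=row["country"],
            event_date=_date(row["event_date"]),
        )
    for row in _rows("drugs.tsv"):
        cases[row["case_id"]].drugs.append(
            DrugEntry(
                raw_name=row["raw_name"],
                role=row["role"],
                ingredient=row["ingredient"] or None,
                start_date=_date(row["start_date"]),
                indication_pt=row["indication_pt"] or None,
            )
        )
    for row in _rows("reactions.tsv"):
        cases[row["case_id"]].reactions.append(
            ReactionEntry(
                pt=row["pt"],
                group=row["group"] or None,
                onset_date=_date(row["onset_date"]),
            )
        )
    for row in _rows("outcomes.tsv"):
        cases[row["case_id"]].outcomes.add(row["code"])
    return [cases[cid] for cid in sorted(cases)]
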