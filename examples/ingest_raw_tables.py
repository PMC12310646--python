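"""Ingesting raw report tables and serializing the unified case store.

Builds a miniature FAERS-dialect quarter (including a duplicate report
version and an orphan child row), parses it, deduplicates, and writes the
normalized store as a directory of TSVs with a JSON manifest.
"""

import tempfile
from pathlib import Path

from pvsignals import deduplicate_cases, parse_faers_quarter, read_store, write_store
from pvsignals.report_store import DedupStats

DEMO = """primaryid$caseid$fda_dt$event_dt$age$age_cod$sex$occp_cod
1001$100$20230101$20221220$64$YR$F$MD
1002$100$20230301$20221220$64$YR$F$MD
2001$200$20230115$20230110$58$YR$M$PH
"""
DRUG = """primaryid$caseid$drug_seq$role_cod$drugname$start_dt
1001$100$1$PS$KEYTRUDA$20221101
1002$100$1$PS$KEYTRUDA$20221101
2001$200$1$PS$nivolumab$20221215
9999$999$1$PS$orphan drug$
"""
REAC = """primaryid$caseid$pt
1001$100$Encephalitis autoimmune
1002$100$Encephalitis autoimmune
2001$200$Myasthenia gravis
"""

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    (tmp / "demo.txt").write_text(DEMO)
    (tmp / "drug.txt").write_text(DRUG)
    (tmp / "reac.txt").write_text(REAC)
    raw = parse_faers_quarter(
        {"DEMO": tmp / "demo.txt", "DRUG": tmp / "drug.txt", "REAC": tmp / "reac.txt"},
        quarter_label="2023Q1",
    )
    stats = DedupStats()
    cases = deduplicate_cases(raw, stats=stats)
    print(f"demo rows: {stats.n_demo_rows}, cases: {stats.n_cases}, "
          f"stale versions dropped: {stats.n_versions_dropped}, "
          f"orphan rows: {stats.n_orphan_rows}")
    for c in cases:
        print(f"  case {c.case_id}: {c.sex}, age {c.age_years}, "
              f"{[d.raw_name for d in c.drugs]} -> {[r.pt for r in c.reactions]}")
    store_dir = tmp / "store"
    write_store(cases, store_dir, source="FAERS",
                manifest_extra={"versions_dropped": stats.n_versions_dropped})
    assert read_store(store_dir) == cases
    print(f"store round-trips through {[p.name for p in sorted(store_dir.iterdir())]}")
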