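"""Parsing, deduplication and store round-trip behaviour."""

import datetime

import pytest

from pvsignals.report_store import (
    DedupStats,
    age_group_of,
    age_to_years,
    deduplicate_cases,
    parse_faers_quarter,
    parse_jader_tables,
    parse_partial_date,
    read_store,
    write_store,
)
from pvsignals.synthetic_data import (
    SimulationConfig,
    simulate_database,
    write_faers_dialect,
    write_jader_dialect,
)


def _write(path, text):
    path.write_text(text)
    return path


def _faers_paths(tmp_path, demo, drug="primaryid$caseid$drug_seq$role_cod$drugname$start_dt\n",
                 reac="primaryid$caseid$pt\n"):
    return {
        "DEMO": _write(tmp_path / "demo.txt", demo),
        "DRUG": _write(tmp_path / "drug.txt", drug),
        "REAC": _write(tmp_path / "reac.txt", reac),
    }


class TestFaersParsing:
    def test_header_and_fields_parsed_lowercase(self, tmp_path):
        paths = _faers_paths(
            tmp_path, "PRIMARYID$CASEID$AGE$SEX\n1001$100$64$F\n"
        )
        raw = parse_faers_quarter(paths, "2019Q3")
        assert raw.demo_rows == [{"primaryid": "1001", "caseid": "100", "age": "64", "sex": "F"}]
        assert raw.quarter_label == "2019Q3"

    def test_malformed_rows_skipped_and_counted(self, tmp_path):
        demo = "primaryid$caseid$age$sex\n1$1$64$F\n2$2$50\n3$3$70$M\n4$4$20$F\n"
        raw = parse_faers_quarter(_faers_paths(tmp_path, demo))
        assert len(raw.demo_rows) == 3
        assert raw.n_skipped["demo"] == 1

    def test_missing_required_table_is_fatal(self, tmp_path):
        paths = _faers_paths(tmp_path, "primaryid$caseid\n")
        del paths["REAC"]
        with pytest.raises(FileNotFoundError, match="REAC"):
            parse_faers_quarter(paths)

    def test_empty_file_yields_empty_table(self, tmp_path):
        paths = _faers_paths(tmp_path, "")
        raw = parse_faers_quarter(paths)
        assert raw.demo_rows == []


class TestJaderParsing:
    def test_quoted_comma_preserved(self, tmp_path):
        paths = {
            "demo": _write(tmp_path / "demo.csv", 'case_id,sex\n1,"F"\n'),
            "drug": _write(
                tmp_path / "drug.csv", 'case_id,role,drug_name\n1,PS,"nivolumab, injection"\n'
            ),
            "reac": _write(tmp_path / "reac.csv", "case_id,pt\n1,headache\n"),
        }
        raw = parse_jader_tables(paths)
        assert raw.drug_rows[0]["drug_name"] == "nivolumab, injection"
        assert raw.source == "JADER" and raw.outc_rows == []

    def test_undecodable_bytes_report_offset(self, tmp_path):
        p = tmp_path / "demo.csv"
        p.write_bytes(b"case_id,sex\n1,\xff\n")
        paths = {
            "demo": p,
            "drug": _write(tmp_path / "drug.csv", "case_id\n"),
            "reac": _write(tmp_path / "reac.csv", "case_id\n"),
        }
        with pytest.raises(ValueError, match="offset 14"):
            parse_jader_tables(paths, encoding="utf-8")

    def test_fallback_encoding_selectable(self, tmp_path):
        p = tmp_path / "demo.csv"
        p.write_bytes("case_id,sex\n1,F\n".encode("cp932"))
        paths = {
            "demo": p,
            "drug": _write(tmp_path / "drug.csv", "case_id\n"),
            "reac": _write(tmp_path / "reac.csv", "case_id\n"),
        }
        raw = parse_jader_tables(paths, encoding="cp932")
        assert raw.demo_rows[0]["sex"] == "F"


class TestDeduplication:
    def test_latest_receipt_date_version_survives(self, tmp_path):
        demo = (
            "primaryid$caseid$fda_dt$sex\n"
            "1001$100$20230101$F\n"
            "1002$100$20230301$M\n"
        )
        drug = "primaryid$caseid$role_cod$drugname\n1001$100$PS$opdivo\n1002$100$PS$opdivo\n"
        reac = "primaryid$caseid$pt\n1001$100$headache\n1002$100$myositis\n"
        raw = parse_faers_quarter(_faers_paths(tmp_path, demo, drug, reac))
        cases = deduplicate_cases(raw)
        assert len(cases) == 1
        assert cases[0].sex == "M"  # version from 20230301
        assert [r.pt for r in cases[0].reactions] == ["myositis"]

    def test_tie_broken_by_larger_report_sequence(self, tmp_path):
        demo = "primaryid$caseid$fda_dt$sex\n1002$100$20230101$M\n1001$100$20230101$F\n"
        raw = parse_faers_quarter(_faers_paths(tmp_path, demo))
        cases = deduplicate_cases(raw)
        assert cases[0].sex == "M"

    def test_single_case_unchanged(self, tmp_path):
        demo = "primaryid$caseid$fda_dt$sex\n1$1$20230101$F\n"
        raw = parse_faers_quarter(_faers_paths(tmp_path, demo))
        assert len(deduplicate_cases(raw)) == 1

    def test_orphan_child_rows_dropped_and_counted(self, tmp_path):
        demo = "primaryid$caseid$fda_dt\n1$1$20230101\n"
        drug = "primaryid$caseid$role_cod$drugname\n999$9$PS$opdivo\n"
        raw = parse_faers_quarter(_faers_paths(tmp_path, demo, drug))
        stats = DedupStats()
        cases = deduplicate_cases(raw, stats=stats)
        assert stats.n_orphan_rows == 1
        assert cases[0].drugs == []

    def test_conservation_and_planted_versions(self, tmp_path):
        """With 10% injected duplicates of 200 cases, exactly 200 survive,
        each being the planted latest version."""
        cfg = SimulationConfig(n_cases=200, duplicate_rate=0.1, seed=3)
        store, truth = simulate_database(cfg)
        paths = write_faers_dialect(store, truth, tmp_path)
        raw = parse_faers_quarter(paths)
        assert len(raw.demo_rows) > 200
        stats = DedupStats()
        cases = deduplicate_cases(raw, stats=stats)
        assert len(cases) == 200 == stats.n_cases
        assert {c.case_id for c in cases} == set(truth.latest_version)
        # surviving version id matches the planted one
        for c in cases:
            assert str(c.version_key[1]) == truth.latest_version[c.case_id]

    def test_dedup_idempotent(self, tmp_path):
        cfg = SimulationConfig(n_cases=100, duplicate_rate=0.2, seed=5)
        store, truth = simulate_database(cfg)
        paths = write_faers_dialect(store, truth, tmp_path / "one")
        once = deduplicate_cases(parse_faers_quarter(paths))
        # a store written from deduplicated cases has no versions to drop
        truth2 = type(truth)(
            n_cases=truth.n_cases, cell_counts=truth.cell_counts, rr=truth.rr,
            latest_version=truth.latest_version, onset_days=truth.onset_days,
            duplicated_cases=frozenset(),
        )
        paths2 = write_faers_dialect(once, truth2, tmp_path / "two")
        twice = deduplicate_cases(parse_faers_quarter(paths2))
        assert twice == once


class TestRoundTrip:
    def test_faers_round_trip_field_by_field(self, tmp_path):
        cfg = SimulationConfig(n_cases=50, duplicate_rate=0.1, seed=11)
        store, truth = simulate_database(cfg)
        paths = write_faers_dialect(store, truth, tmp_path)
        cases = deduplicate_cases(parse_faers_quarter(paths))
        assert cases == sorted(store, key=lambda c: c.case_id)

    def test_jader_round_trip_content(self, tmp_path):
        cfg = SimulationConfig(n_cases=20, duplicate_rate=0.1, seed=13)
        store, truth = simulate_database(cfg)
        paths = write_jader_dialect(store, truth, tmp_path)
        cases = deduplicate_cases(parse_jader_tables(paths))
        assert len(cases) == 20
        by_id = {c.case_id: c for c in store}
        for c in cases:
            g = by_id[c.case_id]
            assert (c.sex, c.age_years, c.event_date) == (g.sex, g.age_years, g.event_date)
            assert [(d.raw_name, d.role, d.start_date) for d in c.drugs] == [
                (d.raw_name, d.role, d.start_date) for d in g.drugs
            ]
            assert [(r.pt, r.onset_date) for r in c.reactions] == [
                (r.pt, r.onset_date) for r in g.reactions
            ]
            assert c.outcomes == set()  # no outcome table in this dialect

    def test_store_tsv_serialization_round_trip(self, tmp_path, sim_store):
        _, store, _ = sim_store
        write_store(store, tmp_path, source="FAERS")
        assert read_store(tmp_path) == sorted(store, key=lambda c: c.case_id)


class TestFieldHarmonization:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("20230301", (20230301, datetime.date(2023, 3, 1))),
            ("202303", (20230300, None)),
            ("2023", (20230000, None)),
            ("", (0, None)),
            ("20231301", (20231301, None)),  # invalid month: sortable, no date
        ],
    )
    def test_partial_dates(self, raw, expected):
        assert parse_partial_date(raw) == expected

    @pytest.mark.parametrize(
        "age,unit,expected",
        [("64", "YR", 64.0), ("6", "MON", 0.5), ("7", "DEC", 70.0),
         ("730.5", "DY", 2.0), ("x", "YR", None), ("5", "FORTNIGHT", None)],
    )
    def test_age_unit_conversion(self, age, unit, expected):
        assert age_to_years(age, unit) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "age,group",
        [(17.9, "<18"), (18, "18-64"), (64.9, "18-64"), (65, "65-84"),
         (84.9, "65-84"), (85, ">85"), (None, "UNK")],
    )
    def test_age_groups_consistent_with_age(self, age, group):
        assert age_group_of(age) == group
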