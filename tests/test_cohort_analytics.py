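"""Trend, time-to-onset, mortality, severity and demographic analyses."""

import datetime
import math

import numpy as np
import pytest
from scipy import stats

from pvsignals.cohort_analytics import (
    annual_trend,
    chi2_2x2,
    demographic_table,
    mortality_rate,
    mortality_rates,
    percentage,
    severity_association,
    spearman_trend,
    time_to_onset,
)
from pvsignals.report_store import CaseReport, DrugEntry, ReactionEntry
from pvsignals.synthetic_data import SimulationConfig, simulate_database
from pvsignals.vocabulary import annotate_store


class TestSpearman:
    def test_strictly_increasing_counts_give_r_one(self):
        years = list(range(2013, 2021))
        r, p = spearman_trend(years, [1, 5, 9, 20, 33, 47, 60, 82])
        assert r == pytest.approx(1.0)
        assert p <= 0.05  # exact enumeration: 2/8!

    def test_mid_rank_ties_match_hand_computation(self):
        r, _ = spearman_trend([1, 2, 3, 4], [10, 10, 20, 30])
        assert r == pytest.approx(0.9487, abs=1e-4)

    def test_equals_rank_then_pearson_brute_force(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(4, 20))
            x = rng.integers(0, 6, size=n).astype(float)
            y = rng.integers(0, 6, size=n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            r, _ = spearman_trend(x, y)
            rx, ry = stats.rankdata(x), stats.rankdata(y)
            assert r == pytest.approx(np.corrcoef(rx, ry)[0, 1], abs=1e-12)

    def test_exact_permutation_p_agrees_with_t_approximation_direction(self):
        x = [1, 2, 3, 4, 5, 6, 7]
        y = [2, 1, 4, 3, 6, 5, 8]
        r_exact, p_exact = spearman_trend(x, y)  # n=7 -> enumeration
        r_approx, p_approx = spearman_trend(x, y, exact_max_n=0)
        assert r_exact == r_approx
        assert (p_exact < 0.05) == (p_approx < 0.05)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            spearman_trend([1, 2], [3, 4])


def _trend_case(cid, year, pt="myasthenia gravis"):
    return CaseReport(
        case_id=cid,
        version_key=(year * 10000 + 101, 1),
        drugs=[DrugEntry("nivolumab", role="PS")],
        reactions=[ReactionEntry(pt)],
    )


class TestAnnualTrend:
    def test_counts_by_report_year_with_zero_fill(self):
        store = [_trend_case(str(i), y) for i, y in enumerate([2018, 2018, 2020, 2021])]
        annotate_store(store)
        res = annual_trend(store)
        assert res.counts == {2018: 2, 2019: 0, 2020: 1, 2021: 1}

    def test_under_three_years_is_an_error(self):
        store = [_trend_case("1", 2020), _trend_case("2", 2021)]
        annotate_store(store)
        with pytest.raises(ValueError, match="3 calendar years"):
            annual_trend(store)


def _tto_case(cid, start_day, onset_day, drug="nivolumab", pt="myasthenia gravis"):
    base = datetime.date(2020, 1, 1)
    start = base + datetime.timedelta(days=start_day) if start_day is not None else None
    onset = base + datetime.timedelta(days=onset_day) if onset_day is not None else None
    return CaseReport(
        case_id=cid,
        drugs=[DrugEntry(drug, role="PS", start_date=start)],
        reactions=[ReactionEntry(pt, onset_date=onset)],
    )


class TestTimeToOnset:
    def test_order_statistic_quartiles(self):
        store = [_tto_case(str(i), 0, d) for i, d in enumerate([10, 20, 30, 40, 50])]
        annotate_store(store)
        summary = time_to_onset(store)["ALL"]
        assert (summary.q1_days, summary.median_days, summary.q3_days) == (20, 30, 40)
        assert summary.n_usable == 5

    def test_same_day_onset_boundary(self):
        store = [_tto_case("1", 5, 5)]
        annotate_store(store)
        assert time_to_onset(store)["ALL"].median_days == 0

    def test_exclusion_accounting(self):
        store = [
            _tto_case("1", 0, 10),
            _tto_case("2", 10, 5),      # negative interval
            _tto_case("3", None, 10),   # undated start
            _tto_case("4", 0, None),    # undated onset
        ]
        annotate_store(store)
        s = time_to_onset(store)["ALL"]
        assert (s.n_usable, s.n_excluded_negative, s.n_excluded_undated) == (1, 1, 2)
        assert s.n_usable + s.n_excluded_negative + s.n_excluded_undated == 4

    def test_histogram_binning(self):
        store = [_tto_case(str(i), 0, d) for i, d in enumerate([0, 29, 30, 65])]
        annotate_store(store)
        s = time_to_onset(store)["ALL"]
        assert s.histogram == {0: 2, 30: 1, 60: 1}

    def test_lognormal_median_recovered(self):
        """Simulated onsets with a 30-day median are recovered within 10%."""
        cfg = SimulationConfig(n_cases=2000, duplicate_rate=0.0, seed=17)
        store, _ = simulate_database(cfg)
        annotate_store(store)
        s = time_to_onset(store)["ALL"]
        assert s.n_usable > 200
        assert abs(s.median_days - 30) / 30 <= 0.10


class TestMortality:
    @pytest.mark.parametrize(
        "deaths,reports,rate",
        [(404, 1319, 30.63), (518, 1845, 28.08), (99, 489, 20.25), (1, 51, 1.96),
         (0, 10, 0.0)],
    )
    def test_rate_arithmetic(self, deaths, reports, rate):
        assert mortality_rate(deaths, reports).rate_pct == rate

    def test_rates_per_group_from_store(self):
        store = [
            CaseReport(case_id="1", reactions=[ReactionEntry("myositis")],
                       outcomes={"DE"}),
            CaseReport(case_id="2", reactions=[ReactionEntry("myositis")],
                       outcomes={"HO"}),
            CaseReport(case_id="3", reactions=[ReactionEntry("polymyositis")],
                       outcomes=set()),
        ]
        annotate_store(store)
        rows = mortality_rates(store)
        assert rows["IMMUNE_MYOPATHY"].deaths == 1
        assert rows["IMMUNE_MYOPATHY"].reports == 3
        assert rows["IMMUNE_MYOPATHY"].rate_pct == pytest.approx(33.33)

    def test_deaths_cannot_exceed_reports(self):
        with pytest.raises(ValueError):
            mortality_rate(5, 3)


class TestSeverity:
    def test_closed_form_chi2(self):
        chi2, p, _ = chi2_2x2([[10, 90], [30, 70]])
        assert chi2 == pytest.approx(12.5)
        assert p < 0.001

    def test_identical_proportions_give_zero(self):
        chi2, p, _ = chi2_2x2([[20, 80], [10, 40]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi2_equals_squared_two_proportion_z(self):
        """On 500 random tables the Pearson statistic equals z² of the
        two-proportion test (algebraic identity)."""
        rng = np.random.default_rng(3)
        for _ in range(500):
            a, b, c, d = (int(v) for v in rng.integers(1, 80, size=4))
            chi2, _, _ = chi2_2x2([[a, b], [c, d]])
            p1, p2 = a / (a + b), c / (c + d)
            pp = (a + c) / (a + b + c + d)
            z = (p1 - p2) / math.sqrt(pp * (1 - pp) * (1 / (a + b) + 1 / (c + d)))
            assert chi2 == pytest.approx(z * z, rel=1e-10)

    def test_association_partitions_and_flags_correction(self, sim_store):
        _, store, _ = sim_store
        out = severity_association(store)
        assert out
        from pvsignals.vocabulary import case_groups, classify_outcome_severity

        for g, row in out.items():
            total = serious = non = unknown = 0
            for case in store:
                if g in case_groups(case):
                    total += 1
                    lab = classify_outcome_severity(case.outcomes)
                    serious += lab == "SERIOUS"
                    non += lab == "NON_SERIOUS"
                    unknown += lab == "UNKNOWN"
            assert serious + non + unknown == total
            assert (row.serious, row.non_serious) == (serious, non)
            assert row.correction in ("none", "fisher")
            assert 0 <= row.p_value <= 1


class TestDemographics:
    def test_sex_split_percentages(self):
        store = [
            CaseReport(case_id=str(i), sex=s,
                       drugs=[DrugEntry("nivolumab", role="PS")],
                       reactions=[ReactionEntry("myositis")])
            for i, s in enumerate(["M", "M", "F", "UNK"])
        ]
        annotate_store(store)
        table = demographic_table(store, strata=("sex",))
        by_level = table.set_index("level")["pct"].to_dict()
        assert by_level == {"M": 50.0, "F": 25.0, "UNK": 25.0}

    def test_percentages_sum_to_100_per_drug_column(self, sim_store):
        _, store, _ = sim_store
        table = demographic_table(store)
        sums = table.groupby(["stratum", "drug"])["pct"].sum()
        assert ((sums - 100).abs() <= 0.2 + 1e-9).all()

    def test_unknown_stratum_rejected(self, sim_store):
        _, store, _ = sim_store
        with pytest.raises(ValueError):
            demographic_table(store, strata=("shoe_size",))


def test_percentage_helper():
    assert percentage(60, 1959) == 3.06
    assert percentage(946, 3999, 1) == 23.7
    with pytest.raises(ZeroDivisionError):
        percentage(1, 0)
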