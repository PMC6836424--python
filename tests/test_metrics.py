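"""Measure suite: frequencies, responses, salience, burden, trend test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_frame
from naive import (
    naive_alert_frequency,
    naive_response_counts,
    naive_threshold_table,
    permutation_trend_pvalue,
)
from pumpwatch.metrics import (
    ConservationError,
    DEFAULT_SHIFT_SCHEME,
    ShiftScheme,
    alert_frequency,
    alert_salience,
    alerts_per_infusion_histogram,
    burden_by_medication,
    burden_by_time,
    chi_square_trend,
    compute_report,
    ders_compliance,
    response_distribution,
    threshold_violation_table,
    unweighted_yearly_mean,
    verify_conservation,
)


def alert_block(n, infusion_ids, responses=None, **cols):
    """n alerts (optionally each followed by a response) as one frame."""
    alerts = make_frame(
        n, infusion_id=infusion_ids, event_type="alert",
        alert_type=cols.pop("alert_type", "soft_max"), **cols,
    )
    if responses is None:
        return alerts
    cols.pop("timestamp", None)
    resp = make_frame(
        n, infusion_id=infusion_ids, event_type="response", response_action=responses,
        timestamp=alerts["timestamp"] + pd.Timedelta(minutes=1), **cols,
    )
    return pd.concat([alerts, resp], ignore_index=True)


class TestAlertFrequency:
    def test_hand_counted_toy_log(self):
        # 10 starts over 8 unique infusions; 3 alerts all on infusion I0:
        # denominator 1 -> 3/10 = 30%, denominator 2 -> 1/8 = 12.5%
        start_ids = [f"I{i}" for i in range(8)] + ["I0", "I1"]
        starts = make_frame(10, infusion_id=start_ids)
        alerts = alert_block(3, ["I0", "I0", "I0"])
        freq = alert_frequency(pd.concat([starts, alerts], ignore_index=True))
        row = freq.loc[2014]
        assert row["n_infusion_starts"] == 10
        assert row["n_unique_infusions"] == 8
        assert row["pct_starts_with_alerts"] == pytest.approx(30.0)
        assert row["pct_infusions_with_alerts"] == pytest.approx(12.5)

    def test_no_alerts_is_zero_under_both_denominators(self):
        freq = alert_frequency(make_frame(5))
        assert freq.loc[2014, "pct_starts_with_alerts"] == 0.0
        assert freq.loc[2014, "pct_infusions_with_alerts"] == 0.0

    def test_all_years_average_is_unweighted_mean_of_percentages(self):
        # yearly rates engineered to 2.80 / 5.40 / 4.90 percent of starts
        blocks = []
        for year, n_alerts in [(2014, 28), (2015, 54), (2016, 49)]:
            ts = pd.Timestamp(f"{year}-06-01 12:00:00")
            ids = [f"S{year}{i}" for i in range(1000)]
            blocks.append(make_frame(1000, timestamp=ts, infusion_id=ids))
            blocks.append(alert_block(n_alerts, ids[:n_alerts], timestamp=ts))
        freq = alert_frequency(pd.concat(blocks, ignore_index=True))
        yearly = freq.loc[[2014, 2015, 2016], "pct_starts_with_alerts"]
        assert list(yearly.round(2)) == [2.80, 5.40, 4.90]
        assert round(freq.loc["all_years", "pct_starts_with_alerts"], 2) == 4.37
        assert unweighted_yearly_mean([2.80, 5.40, 4.90]) == pytest.approx(4.3667, abs=1e-4)

    def test_matches_naive_recount_on_generated_log(self, small_sim):
        _, records, _ = small_sim
        freq = alert_frequency(records)
        starts, unique, alerts, alerting = naive_alert_frequency(records)
        pooled = freq.loc[[y for y in freq.index if y != "all_years"]]
        assert pooled["n_infusion_starts"].sum() == starts
        assert pooled["n_alerts"].sum() == alerts


class TestDersCompliance:
    def test_hand_count(self):
        frame = make_frame(10, mode=["DERS"] * 7 + ["basic"] * 3)
        comp = ders_compliance(frame)
        assert comp.loc[2014, "pct_ders"] == pytest.approx(70.0)
        assert comp.loc[2014, "pct_basic"] == pytest.approx(30.0)

    def test_yearly_89_84_87_averages_to_87(self):
        blocks = []
        for year, n_ders in [(2014, 89), (2015, 84), (2016, 87)]:
            ts = pd.Timestamp(f"{year}-03-01 09:00:00")
            blocks.append(
                make_frame(
                    100, timestamp=ts, infusion_id=[f"S{year}{i}" for i in range(100)],
                    mode=["DERS"] * n_ders + ["basic"] * (100 - n_ders),
                )
            )
        comp = ders_compliance(pd.concat(blocks, ignore_index=True))
        assert comp.loc["all_years", "pct_ders_rounded"] == 87
        assert comp.loc[2014, "pct_ders"] + comp.loc[2014, "pct_basic"] == pytest.approx(100.0)

    def test_all_basic_log(self):
        comp = ders_compliance(make_frame(4, mode="basic"))
        assert comp.loc[2014, "pct_ders"] == 0.0


class TestResponses:
    def test_toy_log_matches_naive_recount(self):
        responses = ["override"] * 4 + ["cancel"] * 3 + ["reprogram"] * 1
        frame = alert_block(8, [f"I{i}" for i in range(8)], responses=responses)
        dist = response_distribution(frame, by=None)
        from pumpwatch.model import frame_to_records

        naive = naive_response_counts(frame_to_records(frame))
        assert dist.loc["pooled", "n_override"] == naive["override"] == 4
        assert dist.loc["pooled", "n_cancel"] == naive["cancel"] == 3
        assert dist.loc["pooled", "n_reprogram"] == naive["reprogram"] == 1
        assert dist.loc["pooled", "pct_override"] == pytest.approx(50.0)

    def test_all_overridden(self):
        frame = alert_block(5, [f"I{i}" for i in range(5)], responses=["override"] * 5)
        dist = response_distribution(frame, by=None)
        assert dist.loc["pooled", "pct_override"] == 100.0
        assert dist.loc["pooled", "pct_cancel"] == 0.0

    def test_percentages_sum_to_100_per_stratum(self, small_sim):
        _, records, _ = small_sim
        dist = response_distribution(records, by="year")
        pct = dist[["pct_override", "pct_cancel", "pct_reprogram"]].sum(axis=1)
        assert np.allclose(pct[dist["n_resolved_alerts"] > 0], 100.0)


class TestSalience:
    def test_all_overridden_is_zero(self):
        frame = alert_block(4, [f"I{i}" for i in range(4)], responses=["override"] * 4)
        assert alert_salience(frame) == 0.0

    def test_all_cancelled_is_one(self):
        frame = alert_block(4, [f"I{i}" for i in range(4)], responses=["cancel"] * 4)
        assert alert_salience(frame) == 1.0

    @settings(max_examples=50, deadline=None)
    @given(
        responses=st.lists(
            st.sampled_from(["override", "cancel", "reprogram"]), min_size=1, max_size=40
        )
    )
    def test_salience_is_one_minus_override_fraction(self, responses):
        n = len(responses)
        frame = alert_block(n, [f"I{i}" for i in range(n)], responses=responses)
        salience = alert_salience(frame)
        override_frac = responses.count("override") / n
        assert salience + override_frac == pytest.approx(1.0)

    def test_by_drug(self):
        frame = pd.concat(
            [
                alert_block(2, ["I1", "I2"], responses=["cancel", "cancel"], drug_name="fentanyl"),
                alert_block(2, ["I3", "I4"], responses=["override", "override"], drug_name="TPN"),
            ],
            ignore_index=True,
        )
        table = alert_salience(frame, by="drug_name")
        assert table.loc["fentanyl", "salience"] == 1.0
        assert table.loc["TPN", "salience"] == 0.0


class TestThresholdTable:
    def test_matches_naive_oracle_on_generated_log(self, small_sim):
        _, records, _ = small_sim
        table = threshold_violation_table(records)
        by_type_year, by_type_resp = naive_threshold_table(records)
        for at in ("soft_min", "hard_min", "soft_max", "hard_max"):
            for col in table.columns:
                if isinstance(col, (int, np.integer)):
                    assert table.loc[at, col] == by_type_year.get((at, col), 0)
            for action in ("cancel", "override", "reprogram"):
                assert table.loc[at, action] == by_type_resp.get((at, action), 0)

    def test_empty_log_gives_all_zero_table(self):
        table = threshold_violation_table(make_frame(0))
        assert (table[["total", "cancel", "override", "reprogram"]] == 0).all().all()

    def test_conservation_on_generated_log(self, small_sim):
        _, records, _ = small_sim
        tallies = verify_conservation(records)
        assert tallies["sum_over_types"] == tallies["total_alerts"]

    def test_conservation_failure_diagnosed(self):
        # a hard_max alert answered by an override breaks the forced-cancel
        # identity and must be flagged
        frame = alert_block(1, ["I1"], responses=["override"], alert_type="hard_max")
        with pytest.raises(ConservationError, match="hard_max"):
            verify_conservation(frame)

    def test_unresolved_alerts_counted_but_not_in_responses(self):
        frame = alert_block(3, ["I1", "I2", "I3"])  # no responses at all
        table = threshold_violation_table(frame)
        assert table.loc["total", "total"] == 3
        assert table.loc["total", ["cancel", "override", "reprogram"]].sum() == 0
        verify_conservation(frame)  # identities hold with unresolved bucket


class TestBurdenByTime:
    def test_hand_classified_six_alerts(self):
        hours = [8, 12, 16, 21, 23, 3]  # day, day, evening, evening, night, night
        ts = [pd.Timestamp(2014, 6, 2 + i, h) for i, h in enumerate(hours)]
        frame = pd.concat(
            [
                make_frame(6, timestamp=ts, infusion_id=[f"I{i}" for i in range(6)]),
                alert_block(6, [f"I{i}" for i in range(6)], timestamp=ts),
            ],
            ignore_index=True,
        )
        shift = burden_by_time(frame)["shift"]
        assert list(shift["n_alerts"]) == [2, 2, 2]
        assert shift["pct_of_alerts"].sum() == pytest.approx(100.0)

    def test_weekend_and_day_of_week(self):
        ts = [pd.Timestamp("2014-06-07 10:00"), pd.Timestamp("2014-06-09 10:00")]  # Sat, Mon
        frame = pd.concat(
            [
                make_frame(2, timestamp=ts, infusion_id=["I0", "I1"]),
                alert_block(2, ["I0", "I1"], timestamp=ts),
            ],
            ignore_index=True,
        )
        tables = burden_by_time(frame)
        assert tables["weekend"].loc["weekend", "n_alerts"] == 1
        assert tables["day_of_week"].loc["Saturday", "n_alerts"] == 1
        assert tables["month"].loc["2014-06", "n_alerts"] == 2

    def test_uniform_times_give_symmetric_shift_shares(self):
        rng = np.random.default_rng(5)
        n = 3000
        ts = pd.Timestamp("2014-01-01") + pd.to_timedelta(rng.uniform(0, 365 * 24, n), unit="h")
        ids = [f"I{i}" for i in range(n)]
        frame = pd.concat(
            [make_frame(n, timestamp=ts, infusion_id=ids), alert_block(n, ids, timestamp=ts)],
            ignore_index=True,
        )
        shift = burden_by_time(frame)["shift"]
        # each 8h shift should hold ~1/3 of alerts; 5 sigma binomial margin
        margin = 5 * 100 * np.sqrt((1 / 3) * (2 / 3) / n)
        assert (np.abs(shift["pct_of_alerts"] - 100 / 3) < margin).all()

    def test_scheme_must_partition_the_clock(self):
        with pytest.raises(ValueError, match="partition"):
            ShiftScheme((("day", 7, 15), ("night", 15, 6)))
        with pytest.raises(ValueError, match="partition"):
            ShiftScheme((("a", 0, 12), ("b", 11, 0)))
        assert DEFAULT_SHIFT_SCHEME.labels == ["day", "evening", "night"]


class TestAlertsPerInfusion:
    def test_single_infusion_single_alert(self):
        table = alerts_per_infusion_histogram(alert_block(1, ["I1"]))
        assert table.loc["1", "n_infusions"] == 1
        assert table["fraction"].sum() == pytest.approx(1.0)

    def test_hand_counted_1_1_2_4(self):
        ids = ["A", "B", "C", "C", "D", "D", "D", "D"]
        table = alerts_per_infusion_histogram(alert_block(8, ids))
        assert list(table["fraction"]) == pytest.approx([0.5, 0.25, 0.0, 0.25])

    def test_empty_when_no_alerts(self):
        assert alerts_per_infusion_histogram(make_frame(3)).empty


class TestBurdenByMedication:
    def test_two_drug_hand_tally(self):
        frame = pd.concat(
            [
                make_frame(10, infusion_id=[f"F{i}" for i in range(10)], drug_name="fentanyl"),
                make_frame(20, infusion_id=[f"T{i}" for i in range(20)], drug_name="TPN"),
                alert_block(4, ["F0", "F0", "F1", "F2"], responses=["override"] * 4,
                            drug_name="fentanyl"),
                alert_block(2, ["T0", "T1"], responses=["cancel", "reprogram"], drug_name="TPN"),
            ],
            ignore_index=True,
        )
        table = burden_by_medication(frame, k=None)
        assert table.loc["fentanyl", "n_alerts"] == 4
        assert table.loc["fentanyl", "alerts_per_100_starts"] == pytest.approx(40.0)
        assert table.loc["TPN", "alerts_per_100_starts"] == pytest.approx(10.0)
        assert table.index[0] == "fentanyl"  # ranked by alerts per start
        assert table.loc["fentanyl", "override_rate"] == 1.0
        assert table.loc["TPN", "salience"] == 1.0
        # fentanyl: 3 alerting infusions, one with 2 alerts
        assert table.loc["fentanyl", "multi_alert_share"] == pytest.approx(1 / 3)

    def test_single_drug_log(self):
        frame = pd.concat(
            [make_frame(5, drug_name="insulin", infusion_id=[f"I{i}" for i in range(5)]),
             alert_block(2, ["I0", "I1"], drug_name="insulin")],
            ignore_index=True,
        )
        table = burden_by_medication(frame, k=3)
        assert list(table.index) == ["insulin"]
        assert table.loc["insulin", "pct_of_all_alerts"] == 100.0


class TestChiSquareTrend:
    def test_identical_proportions_give_null_result(self):
        stat, p = chi_square_trend([5, 10, 15], [50, 100, 150])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_agrees_with_permutation_oracle(self):
        cases = [([30, 40, 52], [200, 200, 200]), ([8, 12, 20], [60, 60, 60])]
        for succ, tot in cases:
            _, p = chi_square_trend(succ, tot)
            p_perm = permutation_trend_pvalue(succ, tot, n_perm=20000, seed=3)
            assert abs(p - p_perm) < 0.02, (succ, p, p_perm)

    def test_large_study_trend_is_highly_significant(self):
        # yearly alert counts and start counts at published scale
        stat, p = chi_square_trend([3888, 4553, 7279], [137423, 85006, 147876])
        assert p < 1e-4
        assert stat > 100

    @pytest.mark.parametrize(
        "succ,tot",
        [([1, 2], [10, 0]), ([5], [10]), ([11, 2], [10, 10]), ([-1, 2], [10, 10])],
    )
    def test_domain_errors(self, succ, tot):
        with pytest.raises(ValueError):
            chi_square_trend(succ, tot)

    def test_degenerate_pooled_proportion(self):
        assert chi_square_trend([0, 0], [10, 10]) == (0.0, 1.0)
        assert chi_square_trend([10, 10], [10, 10]) == (0.0, 1.0)


class TestReportBundle:
    def test_report_computes_and_writes_all_tables(self, small_sim, tmp_path):
        _, records, _ = small_sim
        report = compute_report(records)
        files = report.write(tmp_path)
        names = {p.name for p in files}
        assert "threshold_violations.csv" in names
        assert "alerts_per_infusion.json" in names
        assert (tmp_path / "summary.json").exists()
        assert 0.0 <= report.salience_overall <= 1.0

    def test_report_is_deterministic_given_inputs(self, small_sim, tmp_path):
        _, records, _ = small_sim
        d1, d2 = tmp_path / "a", tmp_path / "b"
        compute_report(records).write(d1)
        compute_report(records).write(d2)
        for p1 in sorted(d1.iterdir()):
            assert p1.read_bytes() == (d2 / p1.name).read_bytes()
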