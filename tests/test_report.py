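import json
import math

import pandas as pd
import pytest

from orderspc import (GeneratorSpec, InsufficientDataError, ObservationSet,
                      Recommendation, build_report, chart_export,
                      generate_compliance_data, load_report, orderings_count,
                      render_text, round_sig, write_report)


class TestOrderingsCount:
    @pytest.mark.parametrize("n,total,distinct", [
        (2, 2, 1),
        (3, 6, 3),
        (23, math.factorial(23), math.factorial(23) // 2),
    ])
    def test_exact_counts(self, n, total, distinct):
        assert orderings_count(n) == (total, distinct)

    def test_23_factorial_printed_value_and_trailing_zeros(self):
        total, _ = orderings_count(23)
        assert total == 25852016738884976640000
        assert round_sig(total, 3) == 2.59e22
        assert str(total).endswith("0000") and not str(total).endswith("00000")

    def test_guard(self):
        with pytest.raises(InsufficientDataError):
            orderings_count(1)


@pytest.fixture(scope="module")
def wards():
    return generate_compliance_data(GeneratorSpec(n=23, seed=9))


@pytest.fixture(scope="module")
def wards_report(wards):
    return build_report(wards, resample=(1500, 4))


class TestBuildReport:
    def test_internal_consistency(self, wards_report):
        r = wards_report
        assert r.width_difference == pytest.approx(r.width_max - r.width_min)
        assert r.width_min == pytest.approx(2 * 2.66 * r.extremal.mr_bar_min)
        assert r.width_max == pytest.approx(2 * 2.66 * r.extremal.mr_bar_max)
        assert r.width_difference_over_range == pytest.approx(
            r.width_difference / r.data_summary["range"])
        assert r.orderings_distinct_upper_bound * 2 == r.orderings_total
        assert set(r.flagged_counts) == {"xmr_min_limits", "xmr_max_limits",
                                         "inner_fences", "outer_fences",
                                         "three_sigma"}
        assert r.flagged_counts["xmr_max_limits"] <= r.flagged_counts["xmr_min_limits"]

    def test_resample_stays_inside_extrema(self, wards_report):
        r = wards_report
        assert r.resample.summary["minimum"] >= r.extremal.mr_bar_min - 1e-9
        assert r.resample.summary["maximum"] <= r.extremal.mr_bar_max + 1e-9

    def test_recommendation_follows_ordering_flag(self, wards):
        assert build_report(wards).recommendation is Recommendation.USE_OUTLIER_METHODS
        ordered = ObservationSet(wards.labels, wards.values,
                                 has_inherent_order=True, unit_label=wards.unit_label)
        assert build_report(ordered).recommendation is Recommendation.USE_XMR

    def test_constant_data_degenerates_gracefully(self):
        obs = ObservationSet(("a", "b", "c"), (5.0, 5.0, 5.0))
        r = build_report(obs)
        assert r.width_min == r.width_max == r.width_difference == 0.0
        assert r.width_difference_over_range is None
        assert all(c == 0 for c in r.flagged_counts.values())

    def test_config_records_method_disclosure(self, wards_report):
        cfg = wards_report.config
        assert cfg["limit_constant"] == 2.66
        assert cfg["quartile_method"] == "hinges"
        assert cfg["resample_seed"] == 4 and cfg["n_resamples"] == 1500

    def test_adding_an_extreme_datum_never_shrinks_width_max(self, rng):
        for _ in range(20):
            values = list(rng.uniform(20, 60, 9))
            obs = ObservationSet([f"w{i}" for i in range(9)], values)
            base = build_report(obs)
            extended = ObservationSet([f"w{i}" for i in range(10)], values + [99.0])
            assert build_report(extended).width_max >= base.width_max - 1e-9


class TestSerialisation:
    def test_json_round_trip_is_identity(self, wards_report, tmp_path):
        p = tmp_path / "report.json"
        write_report(wards_report, p, format="json")
        assert load_report(p) == wards_report

    def test_csv_one_row_per_statistic(self, wards_report, tmp_path):
        p = tmp_path / "report.csv"
        write_report(wards_report, p, format="csv")
        frame = pd.read_csv(p)
        assert list(frame.columns) == ["statistic", "value"]
        stats = set(frame["statistic"])
        assert {"data_summary.mean", "extremal.mr_bar_max",
                "flagged_counts.inner_fences", "width_difference"} <= stats
        assert not frame["statistic"].duplicated().any()

    def test_text_rounds_to_three_significant_figures(self, wards_report, tmp_path):
        p = tmp_path / "report.txt"
        write_report(wards_report, p, format="text")
        text = p.read_text()
        mr_max_3sf = f"{round_sig(wards_report.extremal.mr_bar_max, 3):.3g}"
        assert f"max {mr_max_3sf}" in text
        assert text == render_text(wards_report)


class TestChartExport:
    def test_schema_and_consistency(self, wards, wards_report, tmp_path):
        p = tmp_path / "chart.csv"
        chart_export(wards, wards_report, p)
        frame = pd.read_csv(p)
        assert len(frame) == wards.n
        assert list(frame["value"]) == pytest.approx(list(wards.values))
        center = wards_report.data_summary["mean"]
        assert frame["xmr_max_lower"].iloc[0] == pytest.approx(
            center - 2.66 * wards_report.extremal.mr_bar_max)

    def test_negative_lower_limit_flagged_as_clipped(self, tmp_path):
        # Data whose mR_max limit falls below 0 on the percentage scale
        values = (5.0, 60.0, 10.0, 70.0, 8.0, 65.0)
        obs = ObservationSet([f"w{i}" for i in range(6)], values,
                             unit_label="% compliance")
        rep = build_report(obs)
        p = tmp_path / "chart.csv"
        chart_export(obs, rep, p)
        frame = pd.read_csv(p)
        assert frame["xmr_max_lower"].iloc[0] < 0
        assert bool(frame["xmr_max_lower_clipped"].iloc[0])
        assert not bool(frame["xmr_min_upper_clipped"].iloc[0]) or \
            not 0 <= frame["xmr_min_upper"].iloc[0] <= 100
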