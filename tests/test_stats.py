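"""Phase-comparison statistics: Wilcoxon, Lilliefors, Bonferroni, summary."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from fwavetilt.stats import (ComparisonGraph, classify_response, compare_phases,
                             lilliefors, summarize, wilcoxon_bruteforce,
                             wilcoxon_signed_rank)

PHASES = ("B1", "B2", "HDT1", "HDT2", "HUT1", "HUT2")


def _cohort(rng, n=24, ff_by_phase=None, noise=0.05):
    rows = []
    base = rng.normal(6.7, 0.3, n)
    for pid in range(n):
        for ph in PHASES:
            shift = 0.0 if ff_by_phase is None else ff_by_phase.get(ph, 0.0)
            rows.append({"patient": f"p{pid}", "phase": ph,
                         "ff": base[pid] + shift + rng.normal(0, noise)})
    return pd.DataFrame(rows)


class TestWilcoxon:
    def test_identical_pairs(self):
        x = np.arange(10.0)
        with pytest.warns(UserWarning, match="zero"):
            assert wilcoxon_signed_rank(x, x) == 1.0

    def test_all_positive_n8_exact(self):
        x = np.arange(1.0, 9.0)
        assert wilcoxon_signed_rank(x, np.zeros(8)) == pytest.approx(2 / 256)

    def test_exact_matches_bruteforce_enumeration(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 11))
            x = rng.normal(0, 1, n)
            y = rng.normal(0.3, 1, n)
            assert wilcoxon_signed_rank(x, y) == pytest.approx(
                wilcoxon_bruteforce(x, y), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 15))
            x = rng.normal(0, 1, n)
            y = rng.normal(0.2, 1, n)
            ours = wilcoxon_signed_rank(x, y)
            ref = spstats.wilcoxon(x, y, mode="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_large_n_normal_approximation(self, rng):
        x = rng.normal(0, 1, 40)
        y = x + rng.normal(0.4, 0.5, 40)
        p = wilcoxon_signed_rank(x, y)
        ref = spstats.wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=0.01)


class TestLilliefors:
    def test_power_against_exponential(self, rng):
        # a heavily skewed alternative is rejected far above the 5 % level
        hits = sum(lilliefors(rng.exponential(1.0, 24)) < 0.05 for _ in range(200))
        assert hits > 0.5 * 200

    def test_matches_reference_implementation(self, rng):
        from statsmodels.stats.diagnostic import lilliefors as sm_lilliefors

        for _ in range(20):
            x = rng.exponential(1.0, 24) if rng.random() < 0.5 else rng.normal(0, 1, 24)
            p_ref = sm_lilliefors(x, dist="norm", pvalmethod="table")[1]
            p = lilliefors(x)
            if p_ref <= 0.001 or p_ref >= 0.2:  # table saturates outside
                continue
            assert p == pytest.approx(p_ref, abs=0.02)

    def test_degenerate_sample_missing(self):
        with pytest.warns(UserWarning, match="degenerate"):
            assert np.isnan(lilliefors(np.full(10, 3.0)))

    def test_small_sample_missing(self):
        assert np.isnan(lilliefors(np.array([1.0, 2.0, 3.0])))


class TestComparePhases:
    def test_default_graph_and_threshold(self, rng):
        df = _cohort(rng)
        res = compare_phases(df, metric_names=("ff",))
        assert len(res) == 9
        assert np.allclose(res["threshold"], 0.05 / 9)

    def test_injected_step_detected_null_controlled(self, rng):
        hits_step = hits_null = 0
        n_rep = 100
        for _ in range(n_rep):
            df = _cohort(rng, ff_by_phase={"HDT1": -0.2, "HDT2": -0.2})
            res = compare_phases(df, metric_names=("ff",)).set_index(
                ["phase_a", "phase_b"])
            hits_step += bool(res.loc[("B2", "HDT1"), "significant"])
            hits_null += bool(res.loc[("B1", "B2"), "significant"])
        assert hits_step >= 0.9 * n_rep
        assert hits_null <= 0.05 * n_rep

    def test_identical_metrics_nothing_significant(self):
        rows = [{"patient": f"p{i}", "phase": ph, "ff": 6.7}
                for i in range(10) for ph in PHASES]
        res = compare_phases(pd.DataFrame(rows), metric_names=("ff",))
        assert not res["significant"].any()

    def test_bonferroni_monotone_in_graph_size(self, rng):
        df = _cohort(rng, ff_by_phase={"HDT1": -0.08})
        small = ComparisonGraph(pairs=[("B2", "HDT1")])
        full = ComparisonGraph()
        r_small = compare_phases(df, small, metric_names=("ff",))
        r_full = compare_phases(df, full, metric_names=("ff",)).set_index(
            ["phase_a", "phase_b"])
        # same p-value, stricter threshold: enlarging the graph can only
        # remove significance
        if not r_small["significant"].iloc[0]:
            assert not r_full.loc[("B2", "HDT1"), "significant"]

    def test_pairwise_deletion(self, rng):
        df = _cohort(rng)
        extra = pd.DataFrame([{"patient": "px", "phase": ph,
                               "ff": 6.5 if ph != "HUT2" else np.nan}
                              for ph in PHASES])
        r1 = compare_phases(df, metric_names=("ff",))
        r2 = compare_phases(pd.concat([df, extra]), metric_names=("ff",))
        merged = r1.merge(r2, on=["phase_a", "phase_b"], suffixes=("_1", "_2"))
        involves_hut2 = (merged["phase_a"] == "HUT2") | (merged["phase_b"] == "HUT2")
        assert (merged.loc[involves_hut2, "n_2"]
                == merged.loc[involves_hut2, "n_1"]).all()
        assert (merged.loc[~involves_hut2, "n_2"]
                == merged.loc[~involves_hut2, "n_1"] + 1).all()


class TestClassifyAndSummary:
    @pytest.mark.parametrize("prev,cur,expected", [
        (6.70, 6.73, "minimal"),
        (6.70, 6.90, "increase"),
        (100.0, 98.0, "decrease"),
    ])
    def test_response_classes(self, prev, cur, expected):
        assert classify_response(cur, prev) == expected

    def test_zero_previous_uses_cohort_scale(self):
        with pytest.warns(UserWarning, match="cohort"):
            assert classify_response(0.005, 0.0, cohort_median=10.0) == "minimal"

    def test_constant_column_summary(self):
        rows = [{"patient": f"p{i}", "phase": "B1", "ff": 5.0} for i in range(12)]
        s = summarize(pd.DataFrame(rows), metric_names=("ff",))
        row = s.iloc[0]
        assert row["sd"] == 0.0
        assert row["q1"] == row["q3"] == 5.0

    def test_order_statistics_small_sample(self):
        rows = [{"patient": f"p{i}", "phase": "B1", "ff": v}
                for i, v in enumerate([1.0, 2.0, 3.0, 4.0, 5.0])]
        s = summarize(pd.DataFrame(rows), metric_names=("ff",)).iloc[0]
        assert s["median"] == 3.0
        assert s["q1"] == 2.0 and s["q3"] == 4.0

    def test_gaussian_cohort_summary_near_truth(self, rng):
        df = _cohort(rng)
        s = summarize(df, metric_names=("ff",))
        assert np.all(np.abs(s["median"] - 6.7) < 0.25)
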