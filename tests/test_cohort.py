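import math

import numpy as np
import pandas as pd
import pytest

from coagxa.cohort import (
    CohortError,
    fisher_exact,
    group_compare,
    linear_trend,
    odds_ratio_ci,
    percentile_cutoff,
    prevalence_table,
    risk_analysis,
    run_cohort,
    subgroup_masks,
)
from coagxa.composition import FACTOR_NAMES
from coagxa.synthetic import fixture_compositions


def hand_fisher(a, b, c, d):
    """Independent two-sided Fisher p: full hypergeometric enumeration."""
    def log_fact(n):
        return math.lgamma(n + 1)

    def table_logp(a_, b_, c_, d_):
        n = a_ + b_ + c_ + d_
        return (
            log_fact(a_ + b_) + log_fact(c_ + d_) + log_fact(a_ + c_)
            + log_fact(b_ + d_) - log_fact(n) - log_fact(a_)
            - log_fact(b_) - log_fact(c_) - log_fact(d_)
        )

    row1, col1 = a + b, a + c
    obs = table_logp(a, b, c, d)
    p = 0.0
    for a_ in range(max(0, col1 - (c + d)), min(row1, col1) + 1):
        lp = table_logp(a_, row1 - a_, col1 - a_, (c + d) - (col1 - a_))
        if lp <= obs + 1e-9:
            p += math.exp(lp)
    return p


class TestPercentileCutoff:
    def test_uniform_grid(self):
        values = np.arange(1, 101)
        cut = percentile_cutoff(values, 90)
        assert cut == 90
        assert (values > cut).sum() == 10

    def test_all_equal_nothing_above(self):
        values = np.full(50, 7.0)
        cut = percentile_cutoff(values)
        assert (values > cut).sum() == 0

    def test_nearest_rank_899(self, rng):
        values = rng.normal(size=899)
        cut = percentile_cutoff(values, 90)
        assert (values > cut).sum() in (89, 90)

    def test_small_n_rejected(self):
        with pytest.raises(CohortError):
            percentile_cutoff(np.arange(5))

    def test_bad_q_rejected(self):
        with pytest.raises(CohortError):
            percentile_cutoff(np.arange(20), q=100)


class TestOddsRatio:
    @pytest.mark.parametrize(
        "table, or_1dp, ci_1dp",
        [
            ((57, 369, 33, 440), 2.1, (1.3, 3.2)),   # whole population MaxR
            ((6, 34, 1, 89), 15.7, (1.8, 135.0)),    # females w/o OC MaxL
        ],
    )
    def test_printed_tables(self, table, or_1dp, ci_1dp):
        oratio, lo, hi = odds_ratio_ci(*table)
        assert round(oratio, 1) == or_1dp
        assert round(lo, 1) == ci_1dp[0]
        assert round(hi, 0 if ci_1dp[1] > 10 else 1) == ci_1dp[1]

    def test_zero_cell_undefined(self):
        assert odds_ratio_ci(6, 34, 0, 90) == (None, None, None)

    def test_balanced_table_is_one(self):
        oratio, lo, hi = odds_ratio_ci(8, 8, 8, 8)
        assert oratio == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError):
            odds_ratio_ci(-1, 2, 3, 4)

    @pytest.mark.parametrize("a,b,c,d", [(5, 10, 3, 20), (12, 4, 9, 30)])
    def test_invariance_properties(self, a, b, c, d):
        base, _, _ = odds_ratio_ci(a, b, c, d)
        both_swapped, _, _ = odds_ratio_ci(d, c, b, a)
        rows_swapped, _, _ = odds_ratio_ci(c, d, a, b)
        assert both_swapped == pytest.approx(base)
        assert rows_swapped == pytest.approx(1.0 / base)


class TestFisher:
    def test_printed_whole_population_p(self):
        assert fisher_exact(57, 369, 33, 440) == pytest.approx(0.0017, abs=2e-4)

    def test_proportional_table(self):
        assert fisher_exact(10, 90, 10, 90) == pytest.approx(1.0)

    def test_tiny_table_enumeration(self):
        # 3,0,0,3: only 2 of the 20 equally-weighted arrangements are as extreme
        assert fisher_exact(3, 0, 0, 3) == pytest.approx(0.1)

    @pytest.mark.parametrize("table", [(3, 0, 0, 3), (5, 2, 1, 7), (4, 9, 6, 2)])
    def test_matches_hand_enumeration(self, table):
        assert fisher_exact(*table) == pytest.approx(hand_fisher(*table), rel=1e-6)

    @pytest.mark.parametrize("table", [(5, 2, 1, 7), (12, 30, 7, 40)])
    def test_transposition_symmetry(self, table):
        a, b, c, d = table
        assert fisher_exact(a, b, c, d) == pytest.approx(
            fisher_exact(a, c, b, d), rel=1e-9
        )


class TestGroupCompare:
    def test_identical_samples_centered_ci(self, rng):
        x = rng.normal(size=100)
        res = group_compare(x, x.copy())
        assert res["mean_difference"] == pytest.approx(0.0, abs=1e-12)
        if res["diff_ci"] is not None:
            lo, hi = res["diff_ci"]
            assert lo <= 0.0 <= hi

    def test_known_shift_detected(self, rng):
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(1.0, 1.0, 200)
        res = group_compare(b, a)
        assert res["p"] < 1e-3
        if res["test"] == "t-test":
            lo, hi = res["diff_ci"]
            assert lo <= 1.0 <= hi

    def test_skewed_samples_take_nonparametric_branch(self, rng):
        a = rng.lognormal(0.0, 2.0, 300)
        b = rng.lognormal(0.5, 2.0, 300)
        res = group_compare(a, b)
        assert res["test"] == "rank-sum"

    def test_small_group_rejected(self):
        with pytest.raises(CohortError):
            group_compare([1.0, 2.0], [1.0, 2.0, 3.0])


class TestLinearTrend:
    def test_exact_proportionality(self):
        x = np.arange(10, 30, dtype=float)
        res = linear_trend(0.2 * x, x)
        assert res["slope"] == pytest.approx(0.2)
        lo, hi = res["ci"]
        assert hi - lo == pytest.approx(0.0, abs=1e-12)

    def test_recovers_study_scale_bmi_effect(self, rng):
        # BMI-like covariate, effect 0.138 pM/s per unit, n = 450
        x = rng.normal(25.5, 3.8, 450)
        y = 0.138 * x + rng.normal(0, 1.0, 450)
        res = linear_trend(y, x)
        lo, hi = res["ci"]
        assert lo <= 0.138 <= hi

    def test_constant_metric_zero_slope(self):
        x = np.arange(20, dtype=float)
        res = linear_trend(np.full(20, 5.0), x)
        assert res["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(CohortError):
            linear_trend(np.arange(20.0), np.full(20, 3.0))


def cohort_frame(compositions):
    rows = []
    for c in compositions:
        rows.append({
            "subject_id": c.subject_id, "group": c.group or "control",
            "sex": c.sex, "age": c.age, "bmi": c.bmi, "oc_use": c.oc_use,
            **c.levels,
        })
    return pd.DataFrame(rows)


class TestRunCohort:
    def test_printed_individuals_are_distinct(self):
        fx = fixture_compositions()
        df = cohort_frame([fx["individual_1"], fx["individual_2"]])
        m = run_cohort(df)
        assert len(m) == 2
        maxl = m["MaxL"].to_numpy()
        assert maxl[0] != maxl[1]

    def test_empty_cohort(self):
        m = run_cohort(cohort_frame([]))
        assert len(m) == 0

    def test_duplicated_row_identical_metrics(self):
        fx = fixture_compositions()
        df = cohort_frame([fx["individual_1"], fx["individual_1"]])
        m = run_cohort(df)
        assert m.iloc[0][["MaxR", "MaxL", "AUC"]].equals(
            m.iloc[1][["MaxR", "MaxL", "AUC"]]
        )


@pytest.fixture(scope="module")
def toy_metrics():
    rng = np.random.default_rng(7)
    n = 120
    rows = []
    for i in range(n):
        group = "case" if i % 2 else "control"
        sex = "F" if i % 3 else "M"
        rows.append({
            "subject_id": f"s{i}", "group": group, "sex": sex,
            "age": 30 + (i % 40), "bmi": 22 + (i % 10), "oc_use": None,
            "analyte": "fXa",
            "MaxR": rng.normal(8, 3) + (1.5 if group == "case" else 0),
            "TMaxR": 600.0, "MaxL": rng.normal(6, 2), "TMaxL": 1700.0,
            "AUC": rng.normal(15, 5),
        })
    return pd.DataFrame(rows)


class TestPrevalence:
    def test_pooled_above_count(self, toy_metrics):
        cut = percentile_cutoff(toy_metrics["MaxR"], 90)
        r = prevalence_table(toy_metrics, "MaxR", cut)
        assert r.a + r.c == 12  # 10% of 120 by nearest rank on distinct values
        assert r.n_cases + r.n_controls == 120

    def test_sex_partition_sums_to_whole(self, toy_metrics):
        cut = percentile_cutoff(toy_metrics["MaxR"], 90)
        whole = prevalence_table(toy_metrics, "MaxR", cut)
        men = prevalence_table(toy_metrics, "MaxR", cut, "men",
                               toy_metrics["sex"] == "M")
        women = prevalence_table(toy_metrics, "MaxR", cut, "women",
                                 toy_metrics["sex"] == "F")
        for field in ("a", "b", "c", "d"):
            assert getattr(men, field) + getattr(women, field) == getattr(whole, field)

    def test_cutoff_above_max_gives_zero_counts(self, toy_metrics):
        r = prevalence_table(toy_metrics, "MaxR", 1e9)
        assert r.a == 0 and r.c == 0

    def test_single_group_subgroup_rejected(self, toy_metrics):
        with pytest.raises(CohortError):
            prevalence_table(toy_metrics, "MaxR", 0.0, "cases only",
                             toy_metrics["group"] == "case")

    def test_empty_subgroup_rejected(self, toy_metrics):
        with pytest.raises(CohortError):
            prevalence_table(toy_metrics, "MaxR", 0.0, "nobody",
                             pd.Series(False, index=toy_metrics.index))

    def test_risk_analysis_grid(self, toy_metrics):
        cutoffs, results = risk_analysis(toy_metrics)
        assert set(cutoffs) == {"MaxR", "MaxL"}
        labels = {r.subgroup for r in results}
        assert "whole population" in labels and "men" in labels
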