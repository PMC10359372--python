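import itertools

import numpy as np
import pandas as pd
import pytest

from rtnfb.clinical_stats import (
    DegenerateDesignError,
    anova_decomposition,
    baseline_equivalence,
    hedges_g,
    mixed_anova,
    response_remission,
    tukey_posthoc,
)


def brute_force_split_plot(y, groups):
    """Independent oracle: sums of squares by literal enumeration over cells,
    subjects and groups, straight from the textbook definitions."""
    n, k = y.shape
    labels = sorted(set(groups))
    grand = sum(y[i][t] for i in range(n) for t in range(k)) / (n * k)
    ss_total = sum((y[i][t] - grand) ** 2 for i in range(n) for t in range(k))
    subj_mean = [sum(y[i]) / k for i in range(n)]
    group_mean = {
        g: np.mean([y[i][t] for i in range(n) if groups[i] == g for t in range(k)])
        for g in labels
    }
    time_mean = [sum(y[i][t] for i in range(n)) / n for t in range(k)]
    cell_mean = {
        (g, t): np.mean([y[i][t] for i in range(n) if groups[i] == g])
        for g in labels for t in range(k)
    }
    n_g = {g: sum(1 for gg in groups if gg == g) for g in labels}
    ss_group = sum(n_g[g] * k * (group_mean[g] - grand) ** 2 for g in labels)
    ss_subj = sum(k * (subj_mean[i] - grand) ** 2 for i in range(n)) - ss_group
    ss_time = sum(n * (time_mean[t] - grand) ** 2 for t in range(k))
    ss_int = sum(
        n_g[g] * (cell_mean[(g, t)] - group_mean[g] - time_mean[t] + grand) ** 2
        for g in labels for t in range(k)
    )
    ss_err = ss_total - ss_group - ss_subj - ss_time - ss_int
    df_time, df_int, df_err = k - 1, (len(labels) - 1) * (k - 1), (n - len(labels)) * (k - 1)
    f_time = (ss_time / df_time) / (ss_err / df_err)
    f_int = (ss_int / df_int) / (ss_err / df_err)
    return f_time, f_int, ss_err


def long_table(y, groups, scale="madrs"):
    times = ["pre", "mid", "post"]
    rows = [
        {"subject_id": f"s{i:02d}", "group": groups[i], "time": times[t], scale: y[i][t]}
        for i in range(len(y)) for t in range(len(times))
    ]
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_hand_built_table_matches_enumeration_oracle(self):
        y = np.array([
            [28.0, 22.0, 15.0],
            [30.0, 26.0, 20.0],
            [26.0, 21.0, 18.0],
            [29.0, 20.0, 12.0],
            [27.0, 19.0, 14.0],
            [31.0, 24.0, 13.0],
        ])
        groups = ["NFB"] * 3 + ["CBT"] * 3
        f_time, f_int, _ = brute_force_split_plot(y, groups)
        time_res, inter_res = mixed_anova(long_table(y, groups))
        assert time_res.F == pytest.approx(f_time, rel=1e-10)
        assert inter_res.F == pytest.approx(f_int, rel=1e-10)
        assert time_res.df_num == 2 and time_res.df_den == 8
        assert inter_res.df_num == 2 and inter_res.df_den == 8

    def test_matches_pingouin_cross_check(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(42)
        y = rng.normal(25, 4, size=(13, 3))
        y[:7] -= np.array([0, 3, 6])
        groups = ["NFB"] * 7 + ["CBT"] * 6
        table = long_table(y, groups)
        time_res, inter_res = mixed_anova(table)
        aov = pg.mixed_anova(
            data=table, dv="madrs", within="time", subject="subject_id", between="group"
        ).set_index("Source")
        assert time_res.F == pytest.approx(aov.loc["time", "F"], rel=1e-9)
        assert inter_res.F == pytest.approx(aov.loc["Interaction", "F"], rel=1e-9)
        assert time_res.p == pytest.approx(aov.loc["time", "p_unc"], rel=1e-9)
        assert time_res.partial_eta2 == pytest.approx(aov.loc["time", "np2"], rel=1e-9)
        assert time_res.gg_epsilon == pytest.approx(aov.loc["time", "eps"], abs=0.05)

    def test_degenerate_design_rejected(self):
        y = np.full((6, 3), 20.0)
        with pytest.raises(DegenerateDesignError):
            mixed_anova(long_table(y, ["NFB"] * 3 + ["CBT"] * 3))

    def test_ss_identity_and_eta2_consistency(self):
        """SS components sum to SS_total, and partial eta^2 recomputed from F
        and the dfs agrees with the SS-based value."""
        rng = np.random.default_rng(5)
        for _ in range(25):
            y = rng.normal(20, 5, size=(10, 3))
            groups = np.array(["a"] * 5 + ["b"] * 5)
            dec = anova_decomposition(y, groups)
            total = (
                dec["ss_group"] + dec["ss_subj_within"] + dec["ss_time"]
                + dec["ss_interaction"] + dec["ss_error_within"]
            )
            assert total == pytest.approx(dec["ss_total"], rel=1e-8)
            time_res, _ = mixed_anova(long_table(y, list(groups)))
            from_f = (time_res.F * time_res.df_num) / (
                time_res.F * time_res.df_num + time_res.df_den
            )
            assert time_res.partial_eta2 == pytest.approx(from_f, rel=1e-9)

    def test_eta2_ci_brackets_point_estimate(self, clinical_table):
        time_res, _ = mixed_anova(clinical_table)
        lo, hi = time_res.eta2_ci
        assert 0.0 <= lo <= time_res.partial_eta2 <= hi <= 1.0

    def test_incomplete_subjects_dropped(self, clinical_table):
        truncated = clinical_table[
            ~((clinical_table["subject_id"] == "s00") & (clinical_table["time"] == "post"))
        ]
        full = mixed_anova(clinical_table)[0]
        dropped = mixed_anova(truncated)[0]
        assert dropped.df_den == full.df_den - 2  # one subject fewer


class TestTukey:
    def test_identical_time_means_give_p_near_one(self):
        rng = np.random.default_rng(11)
        subj = rng.normal(25, 3, 8)
        y = np.stack([subj + rng.normal(0, 0.8, 8) for _ in range(3)], axis=1)
        y -= y.mean(axis=0, keepdims=True)  # force equal time means
        y += 25
        comps = tukey_posthoc(long_table(y, ["NFB"] * 4 + ["CBT"] * 4))
        assert all(c.p_adjusted > 0.99 for c in comps)

    def test_separated_timepoint_has_smallest_p(self):
        y = np.array([[20.0, 20.1, 10.0]] * 6) + np.arange(6)[:, None]
        y += np.random.default_rng(0).normal(0, 0.05, y.shape)
        comps = {
            (c.level_a, c.level_b): c.p_adjusted
            for c in tukey_posthoc(long_table(y, ["NFB"] * 3 + ["CBT"] * 3))
        }
        assert comps[("pre", "post")] < comps[("pre", "mid")]
        assert comps[("mid", "post")] < comps[("pre", "mid")]

    def test_adjusted_p_at_least_unadjusted(self, clinical_table):
        for c in tukey_posthoc(clinical_table):
            assert c.p_adjusted >= c.p_unadjusted - 1e-12


class TestHedgesG:
    def test_identical_means_give_zero(self):
        res = hedges_g([1.0, 2.0, 3.0], [2.0, 1.0, 3.0])
        assert res.g == pytest.approx(0.0)

    def test_frozen_worked_example(self):
        res = hedges_g([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.d == pytest.approx(-1.5492, abs=1e-4)
        assert res.correction_J == pytest.approx(1 - 3 / 23, abs=1e-10)
        assert res.g == pytest.approx(-1.3472, abs=1e-4)
        assert res.df == 6

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
        assert hedges_g(a, b).g == pytest.approx(-hedges_g(b, a).g, abs=1e-12)

    def test_correction_shrinks_d(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            a, b = rng.normal(0, 1, 6), rng.normal(0.8, 1, 6)
            res = hedges_g(a, b)
            assert abs(res.g) < abs(res.d)
            assert 0 < res.correction_J < 1

    def test_paired_variant(self):
        pre = np.array([28.0, 30, 26, 29, 27, 31])
        post = pre - np.array([10.0, 11, 9, 12, 10, 11])
        res = hedges_g(post, pre, paired=True)
        diff = post - pre
        assert res.d == pytest.approx(diff.mean() / diff.std(ddof=1))
        assert res.df == 5

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError):
            hedges_g([1.0, 1.0], [1.0, 1.0])


def vector_with_moments(mean, sd, n, rng):
    x = rng.normal(0, 1, n)
    x = (x - x.mean()) / x.std(ddof=1)
    return mean + sd * x


class TestBaselineEquivalence:
    def test_identical_distributions_not_significant(self):
        rng = np.random.default_rng(3)
        shared = rng.normal(27, 3, 8)
        rows = []
        for g in ("NFB", "CBT"):
            for i, v in enumerate(shared):
                rows.append({"subject_id": f"{g}{i}", "group": g, "time": "pre",
                             "madrs": v, "bdi": v, "zsrds": v})
        rep = baseline_equivalence(pd.DataFrame(rows))
        assert all(rep[s]["p"] > 0.99 for s in ("madrs", "bdi", "zsrds"))

    def test_flags_iq_and_self_report_gaps(self):
        """Groups built with realistic baseline summary statistics: a 14-point
        IQ gap and a 6-point self-report gap at n=8/8 are significant, a
        1-point clinician-rating gap is not (Welch t from summary stats)."""
        rng = np.random.default_rng(4)
        table = pd.DataFrame(
            [{"subject_id": f"n{i}", "group": "NFB", "time": "pre",
              "madrs": m, "bdi": 27.0, "zsrds": z}
             for i, (m, z) in enumerate(zip(
                 vector_with_moments(27.3, 3.3, 8, rng),
                 vector_with_moments(54.3, 5.7, 8, rng)))]
            + [{"subject_id": f"c{i}", "group": "CBT", "time": "pre",
                "madrs": m, "bdi": 27.0, "zsrds": z}
               for i, (m, z) in enumerate(zip(
                   vector_with_moments(28.4, 2.9, 8, rng),
                   vector_with_moments(48.3, 4.6, 8, rng)))]
        )
        demo = pd.DataFrame(
            [{"subject_id": f"n{i}", "group": "NFB", "iq": v}
             for i, v in enumerate(vector_with_moments(96, 10, 8, rng))]
            + [{"subject_id": f"c{i}", "group": "CBT", "iq": v}
               for i, v in enumerate(vector_with_moments(110, 11, 8, rng))]
        )
        rep = baseline_equivalence(table, demographics=demo, scales=("madrs", "zsrds"))
        # oracle: Welch t from the summary statistics directly
        t_iq = (96 - 110) / np.sqrt((10**2 + 11**2) / 8)
        assert abs(rep["iq"]["statistic"]) == pytest.approx(abs(t_iq), abs=1e-6)
        assert rep["iq"]["p"] < 0.05
        assert rep["zsrds"]["p"] < 0.05
        assert rep["madrs"]["p"] > 0.4

    def test_chi_square_hand_computation(self):
        """2x2 sex table [[8,0],[5,3]]: expected counts 6.5/1.5 per cell row,
        uncorrected chi2 = 3.692 (p ~ 0.055), Yates-corrected 1.641."""
        table = pd.DataFrame(
            [{"subject_id": f"n{i}", "group": "NFB", "time": "pre", "madrs": 27.0}
             for i in range(8)]
            + [{"subject_id": f"c{i}", "group": "CBT", "time": "pre", "madrs": 27.0}
               for i in range(8)]
        )
        demo = pd.DataFrame(
            [{"subject_id": f"n{i}", "group": "NFB", "sex": "f"} for i in range(8)]
            + [{"subject_id": f"c{i}", "group": "CBT",
                "sex": "f" if i < 5 else "m"} for i in range(8)]
        )
        rep = baseline_equivalence(table, demographics=demo, scales=())
        assert rep["sex"]["statistic"] == pytest.approx(1.641, abs=0.01)
        assert rep["sex"]["statistic_uncorrected"] == pytest.approx(3.692, abs=0.01)
        assert rep["sex"]["p_uncorrected"] == pytest.approx(0.0547, abs=0.002)
        assert rep["sex"]["small_expected_counts"]

    def test_single_group_rejected(self):
        table = pd.DataFrame(
            [{"subject_id": "a", "group": "NFB", "time": "pre", "madrs": 20.0}]
        )
        with pytest.raises(ValueError):
            baseline_equivalence(table)


class TestResponseRemission:
    @staticmethod
    def _table(rows):
        return pd.DataFrame(rows)

    def test_no_change_means_no_response(self):
        rows = [
            {"subject_id": "a", "group": "NFB", "time": t, "madrs": 30.0}
            for t in ("pre", "post")
        ] + [
            {"subject_id": "b", "group": "NFB", "time": t, "madrs": 8.0}
            for t in ("pre", "post")
        ]
        out = response_remission(self._table(rows))
        assert out["NFB"]["responders"] == 0
        assert out["NFB"]["remitters"] == 1  # already under the cutoff

    def test_response_threshold_arithmetic(self):
        rows = [
            {"subject_id": "a", "group": "CBT", "time": "pre", "madrs": 30.0},
            {"subject_id": "a", "group": "CBT", "time": "post", "madrs": 14.0},
        ]
        out = response_remission(self._table(rows))
        assert out["CBT"]["responders"] == 1  # 16/30 >= 0.5

    def test_remission_boundary_inclusive(self):
        rows = [
            {"subject_id": "a", "group": "NFB", "time": "pre", "madrs": 30.0},
            {"subject_id": "a", "group": "NFB", "time": "post", "madrs": 9.0},
            {"subject_id": "b", "group": "NFB", "time": "pre", "madrs": 30.0},
            {"subject_id": "b", "group": "NFB", "time": "post", "madrs": 10.0},
        ]
        out = response_remission(self._table(rows))
        assert out["NFB"]["remitters"] == 2

    def test_zero_pre_excluded(self):
        rows = [
            {"subject_id": "a", "group": "NFB", "time": "pre", "madrs": 0.0},
            {"subject_id": "a", "group": "NFB", "time": "post", "madrs": 0.0},
        ]
        out = response_remission(self._table(rows))
        assert out["NFB"]["n"] == 0 and out["NFB"]["n_excluded"] == 1
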