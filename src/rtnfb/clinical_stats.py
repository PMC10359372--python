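"""Clinical inference stage: 2 (group, between) x 3 (time, within) mixed
repeated-measures ANOVA with partial eta squared and a noncentral-F
confidence interval, Tukey post hoc over timepoints, Hedge's g effect sizes
with the small-sample correction, baseline-equivalence tests, and
response/remission summaries.

The ANOVA is a classical sums-of-squares decomposition of the split-plot
design: between-subject variation splits into Group and Subjects-within-
Groups; within-subject variation splits into Time, Group x Time and the
within-subject error, which is the error term for both reported effects.
Sphericity is addressed with the Greenhouse-Geisser correction (reported
alongside the uncorrected test; with three levels the correction is mild).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

logger = logging.getLogger(__name__)

__all__ = [
    "MixedAnovaResult",
    "EffectSizeResult",
    "TukeyComparison",
    "DegenerateDesignError",
    "anova_decomposition",
    "mixed_anova",
    "tukey_posthoc",
    "hedges_g",
    "baseline_equivalence",
    "response_remission",
]

TIME_ORDER = ("pre", "mid", "post")


class DegenerateDesignError(ValueError):
    """No within-cell variance anywhere: the ANOVA error term is zero."""


@dataclass(frozen=True)
class MixedAnovaResult:
    """One effect of the mixed ANOVA."""

    effect: str  # "time" or "group_by_time"
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta2: float
    eta2_ci: tuple[float, float]
    p_gg: float
    gg_epsilon: float
    ss_effect: float
    ss_error: float


@dataclass(frozen=True)
class EffectSizeResult:
    """Standardized mean difference: Cohen's d and Hedge's bias-corrected g."""

    g: float
    d: float
    correction_J: float
    df: int


@dataclass(frozen=True)
class TukeyComparison:
    """One pairwise timepoint contrast with Tukey-adjusted p."""

    level_a: str
    level_b: str
    mean_diff: float
    q: float
    p_adjusted: float
    p_unadjusted: float


def _to_wide(
    table: pd.DataFrame, scale: str, times: Sequence[str] = TIME_ORDER
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Pivot a long clinical table to (subjects x times, group labels, ids).

    Subjects with incomplete timepoint coverage are dropped (listwise) with a
    logged count.
    """
    required = {"subject_id", "group", "time", scale}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"clinical table missing columns: {sorted(missing)}")
    wide = table.pivot_table(
        index=["subject_id", "group"], columns="time", values=scale, aggfunc="first"
    )
    for t in times:
        if t not in wide.columns:
            wide[t] = np.nan
    wide = wide[list(times)]
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if n_dropped:
        logger.info("dropped %d subject(s) with incomplete %s data", n_dropped, scale)
    groups = np.array([g for _, g in complete.index])
    ids = [s for s, _ in complete.index]
    return complete.to_numpy(dtype=float), groups, ids


def anova_decomposition(y: np.ndarray, groups: np.ndarray) -> dict[str, float]:
    """Sums-of-squares decomposition of the split-plot (mixed) design.

    ``y`` is subjects x times; ``groups`` labels each row.  Returns all SS,
    df and mean squares; SS_total = SS_group + SS_subj_within + SS_time +
    SS_interaction + SS_error_within holds exactly.
    """
    y = np.asarray(y, dtype=float)
    n, k = y.shape
    labels = np.unique(groups)
    g_count = len(labels)
    if n < 2 * g_count or k < 2:
        raise ValueError("need >= 2 subjects per group and >= 2 timepoints")
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    subj_means = y.mean(axis=1)
    ss_between_subj = k * float(((subj_means - grand) ** 2).sum())
    ss_group = 0.0
    for g in labels:
        sel = groups == g
        ss_group += sel.sum() * k * (y[sel].mean() - grand) ** 2
    ss_subj_within = ss_between_subj - ss_group

    time_means = y.mean(axis=0)
    ss_time = n * float(((time_means - grand) ** 2).sum())
    ss_interaction = 0.0
    for g in labels:
        sel = groups == g
        cell = y[sel].mean(axis=0)
        ss_interaction += sel.sum() * float(
            ((cell - y[sel].mean() - time_means + grand) ** 2).sum()
        )
    ss_within = ss_total - ss_between_subj
    ss_error = ss_within - ss_time - ss_interaction

    return {
        "ss_total": ss_total,
        "ss_group": float(ss_group),
        "ss_subj_within": float(ss_subj_within),
        "ss_time": ss_time,
        "ss_interaction": float(ss_interaction),
        "ss_error_within": float(ss_error),
        "df_group": g_count - 1,
        "df_subj_within": n - g_count,
        "df_time": k - 1,
        "df_interaction": (g_count - 1) * (k - 1),
        "df_error_within": (n - g_count) * (k - 1),
        "n_subjects": n,
        "n_times": k,
        "n_groups": g_count,
    }


def _gg_epsilon(y: np.ndarray, groups: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    n, k = y.shape
    labels = np.unique(groups)
    dev = np.empty_like(y)
    for g in labels:
        sel = groups == g
        dev[sel] = y[sel] - y[sel].mean(axis=0)
    s = dev.T @ dev / (n - len(labels))
    c = np.eye(k) - np.ones((k, k)) / k
    s_dc = c @ s @ c
    denom = (k - 1) * float((s_dc**2).sum())
    if denom <= 0:
        return 1.0
    eps = float(np.trace(s_dc)) ** 2 / denom
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _eta2_ci(
    f: float, df1: int, df2: int, confidence: float = 0.95
) -> tuple[float, float]:
    """CI for partial eta squared by inverting the noncentral-F distribution
    (pivot the noncentrality, then map lambda / (lambda + df1 + df2 + 1))."""
    alpha = 1.0 - confidence

    def _solve(prob: float) -> float:
        # largest lambda with ncf.cdf(f; lambda) >= prob
        if scipy.stats.ncf.cdf(f, df1, df2, 0.0) < prob:
            return 0.0
        hi = 10.0
        while scipy.stats.ncf.cdf(f, df1, df2, hi) >= prob and hi < 1e6:
            hi *= 2
        return float(
            scipy.optimize.brentq(
                lambda lam: scipy.stats.ncf.cdf(f, df1, df2, lam) - prob, 0.0, hi
            )
        )

    lam_lo = _solve(1.0 - alpha / 2)
    lam_hi = _solve(alpha / 2)
    to_eta = lambda lam: lam / (lam + df1 + df2 + 1)
    return (to_eta(lam_lo), to_eta(lam_hi))


_DEGENERATE_RTOL = 1e-12


def mixed_anova(
    table: pd.DataFrame, scale: str = "madrs"
) -> tuple[MixedAnovaResult, MixedAnovaResult]:
    """Mixed 2 x 3 repeated-measures ANOVA on one clinical scale.

    Returns results for the Time main effect and the Group x Time
    interaction, both tested against the within-subject error term, with
    partial eta squared (and its 95% noncentral-F CI), the uncorrected p and
    the Greenhouse-Geisser corrected p.
    """
    y, groups, _ = _to_wide(table, scale)
    dec = anova_decomposition(y, groups)
    if dec["ss_error_within"] <= _DEGENERATE_RTOL * max(dec["ss_total"], 1.0):
        raise DegenerateDesignError("zero within-cell variance everywhere")
    eps = _gg_epsilon(y, groups)
    ms_error = dec["ss_error_within"] / dec["df_error_within"]

    results = []
    for effect, ss_key, df_key in (
        ("time", "ss_time", "df_time"),
        ("group_by_time", "ss_interaction", "df_interaction"),
    ):
        ss, df1 = dec[ss_key], dec[df_key]
        df2 = dec["df_error_within"]
        f = (ss / df1) / ms_error
        p = float(scipy.stats.f.sf(f, df1, df2))
        p_gg = float(scipy.stats.f.sf(f, df1 * eps, df2 * eps))
        eta2 = ss / (ss + dec["ss_error_within"])
        results.append(
            MixedAnovaResult(
                effect=effect,
                F=float(f),
                df_num=df1,
                df_den=df2,
                p=p,
                partial_eta2=float(eta2),
                eta2_ci=_eta2_ci(f, df1, df2),
                p_gg=p_gg,
                gg_epsilon=eps,
                ss_effect=float(ss),
                ss_error=float(dec["ss_error_within"]),
            )
        )
    return results[0], results[1]


def tukey_posthoc(
    table: pd.DataFrame, scale: str = "madrs"
) -> list[TukeyComparison]:
    """Tukey HSD over the three timepoints using the within-subject error.

    q = |mean_i - mean_j| / sqrt(MS_error / N); adjusted p from the
    studentized range distribution with k means and the error df.
    """
    y, groups, _ = _to_wide(table, scale)
    dec = anova_decomposition(y, groups)
    if dec["ss_error_within"] <= _DEGENERATE_RTOL * max(dec["ss_total"], 1.0):
        raise DegenerateDesignError("zero within-cell variance everywhere")
    n, k = y.shape
    ms_error = dec["ss_error_within"] / dec["df_error_within"]
    df_error = dec["df_error_within"]
    se_q = np.sqrt(ms_error / n)
    means = y.mean(axis=0)
    out = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        q = abs(diff) / se_q if se_q > 0 else np.inf
        p_adj = float(scipy.stats.studentized_range.sf(q, k, df_error))
        t = abs(diff) / (np.sqrt(2.0) * se_q) if se_q > 0 else np.inf
        p_unc = float(2 * scipy.stats.t.sf(t, df_error))
        out.append(
            TukeyComparison(
                level_a=TIME_ORDER[i],
                level_b=TIME_ORDER[j],
                mean_diff=float(diff),
                q=float(q),
                p_adjusted=min(p_adj, 1.0),
                p_unadjusted=min(p_unc, 1.0),
            )
        )
    return out


def hedges_g(
    sample_a: Sequence[float],
    sample_b: Sequence[float],
    paired: bool = False,
) -> EffectSizeResult:
    """Hedge's g: Cohen's d with the small-sample bias correction
    J = 1 - 3 / (4 df - 1).

    Default is the pooled-SD two-sample formula with df = n_a + n_b - 2;
    ``paired=True`` uses the change-score formula (mean of differences over
    the SD of differences, df = n - 1).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if paired:
        if len(a) != len(b) or len(a) < 2:
            raise ValueError("paired samples must have equal length >= 2")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            raise ValueError("undefined effect size: zero SD of differences")
        d = float(diff.mean() / sd)
        df = len(a) - 1
    else:
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each sample needs length >= 2")
        df = len(a) + len(b) - 2
        pooled_var = (
            (len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)
        ) / df
        if pooled_var == 0:
            raise ValueError("undefined effect size: zero pooled SD")
        d = float((a.mean() - b.mean()) / np.sqrt(pooled_var))
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    return EffectSizeResult(g=j * d, d=d, correction_J=j, df=df)


def baseline_equivalence(
    table: pd.DataFrame,
    demographics: pd.DataFrame | None = None,
    scales: Sequence[str] = ("madrs", "bdi", "zsrds"),
) -> dict[str, dict]:
    """Baseline (pre-treatment) group-equivalence tests.

    Continuous variables: Welch two-sample t test.  Categorical demographic
    variables: chi-square on the contingency table, with a small-count
    warning when any expected cell is below 5.  Mirrors a baseline
    characteristics table's p column.
    """
    groups = sorted(table["group"].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    pre = table[table["time"] == "pre"]
    report: dict[str, dict] = {}
    for scale in scales:
        if scale not in pre.columns:
            continue
        a = pre.loc[pre["group"] == groups[0], scale].dropna().to_numpy(float)
        b = pre.loc[pre["group"] == groups[1], scale].dropna().to_numpy(float)
        res = scipy.stats.ttest_ind(a, b, equal_var=False)
        report[scale] = {
            "test": "welch_t",
            "statistic": float(res.statistic),
            "p": float(res.pvalue),
            "mean_by_group": {groups[0]: float(a.mean()), groups[1]: float(b.mean())},
        }
    if demographics is not None:
        merged = demographics
        for col in merged.columns:
            if col in ("subject_id", "group"):
                continue
            by_group = [
                merged.loc[merged["group"] == g, col].dropna() for g in groups
            ]
            if pd.api.types.is_numeric_dtype(merged[col]):
                res = scipy.stats.ttest_ind(
                    by_group[0].to_numpy(float), by_group[1].to_numpy(float),
                    equal_var=False,
                )
                report[col] = {
                    "test": "welch_t",
                    "statistic": float(res.statistic),
                    "p": float(res.pvalue),
                }
            else:
                contingency = pd.crosstab(merged["group"], merged[col]).to_numpy()
                chi2 = scipy.stats.chi2_contingency(contingency)
                chi2_unc = scipy.stats.chi2_contingency(contingency, correction=False)
                small = bool((chi2.expected_freq < 5).any())
                report[col] = {
                    "test": "chi_square",
                    "statistic": float(chi2.statistic),
                    "p": float(chi2.pvalue),
                    "statistic_uncorrected": float(chi2_unc.statistic),
                    "p_uncorrected": float(chi2_unc.pvalue),
                    "small_expected_counts": small,
                }
                if small:
                    logger.warning(
                        "chi-square for %r has expected counts < 5", col
                    )
    return report


def response_remission(
    table: pd.DataFrame,
    scale: str = "madrs",
    response_frac: float = 0.5,
    remission_cutoff: float = 10.0,
) -> dict[str, dict]:
    """Response ((pre - post)/pre >= response_frac) and remission
    (post <= cutoff, boundary inclusive) counts per group.

    Subjects lacking a pre or post score, or with pre = 0, are excluded
    (logged).  The cutoff default is a conventional MADRS remission
    threshold; it is a parameter, not a fixed property of the instrument.
    """
    out: dict[str, dict] = {}
    for group, sub in table.groupby("group"):
        wide = sub.pivot_table(
            index="subject_id", columns="time", values=scale, aggfunc="first"
        )
        n_total = len(wide)
        if "pre" not in wide.columns or "post" not in wide.columns:
            out[str(group)] = {"n": 0, "responders": 0, "remitters": 0}
            continue
        wide = wide.dropna(subset=["pre", "post"])
        zero_pre = wide["pre"] == 0
        if zero_pre.any():
            logger.info(
                "excluded %d subject(s) with pre = 0 in group %s",
                int(zero_pre.sum()), group,
            )
        wide = wide[~zero_pre]
        n = len(wide)
        responders = int(((wide["pre"] - wide["post"]) / wide["pre"] >= response_frac).sum())
        remitters = int((wide["post"] <= remission_cutoff).sum())
        out[str(group)] = {
            "n": n,
            "n_excluded": n_total - n,
            "responders": responders,
            "remitters": remitters,
            "response_rate": responders / n if n else float("nan"),
            "remission_rate": remitters / n if n else float("nan"),
        }
    return out
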