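"""Offline ROI analysis: detrending, per-block up-vs-down percent signal
change, per-half-session averages, and learning-curve estimation.

For each trial the up-regulation window and the preceding down-regulation
window (both shifted by a hemodynamic lag) are averaged and converted to a
percent signal change score

    100 * (mean_up - mean_down) / reference

where the reference is the mean of the lag-shifted preceding down block
(treating down as the local baseline) or, alternatively, the run mean.
Block scores are averaged per half-session for the target ROI, the control
ROI and their difference; the learning curve is the Pearson correlation (and
linear slope) of those per-half-session means against the half-session
number, computed on feedback half-sessions, with transfer half-sessions kept
separate and reported descriptively when too few for a correlation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import scipy.signal
import scipy.stats

from .bold_sim import SimulatedRun
from .paradigm import Condition, CourseSpec, RunSpec, N_DISCARD_OFFLINE

__all__ = [
    "AnalysisConfig",
    "BlockScore",
    "HalfSessionScore",
    "LearningCurveResult",
    "InsufficientDataError",
    "detrend",
    "block_psc",
    "trial_scores",
    "half_session_scores",
    "average_half_sessions",
    "pearson_r",
    "learning_curve",
]

Channel = Literal["target", "control", "diff"]


class InsufficientDataError(ValueError):
    """Too few usable points for the requested statistic."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Offline analysis settings.

    lag_s: hemodynamic lag (s) applied to both block windows.
    detrend: 'linear' removes a least-squares line (mean preserved); 'none'.
    psc_reference: denominator of the block score.
    n_discard: initial volumes excluded from analysis.
    """

    lag_s: float = 5.0
    detrend: Literal["linear", "none"] = "linear"
    psc_reference: Literal["preceding_down_block", "run_mean"] = "preceding_down_block"
    n_discard: int = N_DISCARD_OFFLINE

    def __post_init__(self) -> None:
        if not 0 <= self.lag_s < 20:
            raise ValueError("lag_s must be in [0, 20)")
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")
        if self.detrend not in ("linear", "none"):
            raise ValueError(f"unknown detrend mode: {self.detrend}")
        if self.psc_reference not in ("preceding_down_block", "run_mean"):
            raise ValueError(f"unknown psc_reference: {self.psc_reference}")


@dataclass(frozen=True)
class BlockScore:
    """Up-vs-down percent signal change of one trial for one channel."""

    trial_index: int
    psc_up_vs_down: float
    roi: Channel


@dataclass(frozen=True)
class HalfSessionScore:
    """Across-block means of one half-session (NaN when the run is absent)."""

    half_session: int
    mean_diff: float
    mean_target: float
    mean_control: float
    is_transfer: bool
    n_blocks: int


@dataclass(frozen=True)
class LearningCurveResult:
    """Correlation of per-half-session regulation scores with time.

    r/p/slope refer to the requested channel; r_target, r_control and the
    between-curve correlation are reported alongside.
    """

    r_diff: float
    p_diff: float
    slope: float
    r_target: float
    r_control: float
    r_between_curves: float
    n_points: int
    channel: Channel = "diff"


def detrend(series: Sequence[float] | np.ndarray) -> np.ndarray:
    """Remove the least-squares linear trend, restoring the original mean
    (so percent-signal-change denominators stay valid)."""
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) < 2:
        raise ValueError("series must be 1-D with length >= 2")
    return scipy.signal.detrend(x, type="linear") + x.mean()


def _trial_windows(
    run: RunSpec, config: AnalysisConfig
) -> list[tuple[int, np.ndarray, np.ndarray]]:
    """Lag-shifted (trial_index, down_idx, up_idx) volume windows, clipped to
    the analyzable part of the run; trials with an empty window are dropped."""
    tr = run.tr_s
    n = run.n_volumes
    lo = config.n_discard
    out = []
    downs = [b for b in run.blocks if b.condition is Condition.DOWN]
    ups = [b for b in run.blocks if b.condition is Condition.UP]
    for trial, (down, up) in enumerate(zip(downs, ups), start=1):
        wins = []
        ok = True
        for b in (down, up):
            i0 = int(math.ceil((b.onset_s + config.lag_s) / tr - 1e-9))
            i1 = int(math.ceil((b.end_s + config.lag_s) / tr - 1e-9))
            idx = np.arange(max(i0, lo), min(i1, n))
            if idx.size == 0:
                ok = False
                break
            wins.append(idx)
        if ok:
            out.append((trial, wins[0], wins[1]))
    return out


def block_psc(
    series: Sequence[float] | np.ndarray,
    run: RunSpec,
    config: AnalysisConfig = AnalysisConfig(),
    roi: Channel = "target",
) -> list[BlockScore]:
    """Per-trial up-vs-down percent signal change for one ROI series."""
    x = np.asarray(series, dtype=float)
    if len(x) != run.n_volumes:
        raise ValueError(f"series length {len(x)} != n_volumes {run.n_volumes}")
    valid = slice(config.n_discard, run.n_volumes)
    if config.detrend == "linear" and run.n_volumes - config.n_discard >= 2:
        x = x.copy()
        x[valid] = detrend(x[valid])
    run_mean = float(np.mean(x[valid]))
    windows = _trial_windows(run, config)
    if not windows:
        raise InsufficientDataError("all trials dropped: no usable block windows")
    scores = []
    for trial, down_idx, up_idx in windows:
        mean_down = float(np.mean(x[down_idx]))
        mean_up = float(np.mean(x[up_idx]))
        ref = mean_down if config.psc_reference == "preceding_down_block" else run_mean
        if ref <= 0:
            raise ValueError(f"non-positive PSC reference in trial {trial}")
        scores.append(BlockScore(trial, 100.0 * (mean_up - mean_down) / ref, roi))
    return scores


def trial_scores(
    target: np.ndarray,
    control: np.ndarray,
    run: RunSpec,
    config: AnalysisConfig = AnalysisConfig(),
) -> dict[Channel, list[BlockScore]]:
    """Block scores for target, control and their per-trial difference."""
    t_scores = block_psc(target, run, config, roi="target")
    c_scores = block_psc(control, run, config, roi="control")
    d_scores = [
        BlockScore(t.trial_index, t.psc_up_vs_down - c.psc_up_vs_down, "diff")
        for t, c in zip(t_scores, c_scores)
    ]
    return {"target": t_scores, "control": c_scores, "diff": d_scores}


def half_session_scores(
    course_data: Mapping[int, tuple[np.ndarray, np.ndarray]],
    course: CourseSpec,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[HalfSessionScore]:
    """Across-block mean scores per half-session.

    ``course_data`` maps half-session number -> (target, control) series.
    Half-sessions missing from the mapping yield a NaN score (no imputation).
    """
    out = []
    for hs, _, run in course.iter_runs():
        if hs not in course_data:
            out.append(
                HalfSessionScore(hs, float("nan"), float("nan"), float("nan"),
                                 not run.feedback, 0)
            )
            continue
        target, control = course_data[hs]
        per_channel = trial_scores(np.asarray(target), np.asarray(control), run, config)
        means = {
            ch: float(np.mean([s.psc_up_vs_down for s in scores]))
            for ch, scores in per_channel.items()
        }
        out.append(
            HalfSessionScore(
                half_session=hs,
                mean_diff=means["diff"],
                mean_target=means["target"],
                mean_control=means["control"],
                is_transfer=not run.feedback,
                n_blocks=len(per_channel["diff"]),
            )
        )
    return out


def scores_from_runs(
    runs: Iterable[SimulatedRun],
    course: CourseSpec,
    config: AnalysisConfig = AnalysisConfig(),
) -> list[HalfSessionScore]:
    """Convenience: half-session scores straight from simulated runs."""
    data = {r.half_session: (r.target, r.control) for r in runs}
    return half_session_scores(data, course, config)


def average_half_sessions(
    per_subject: Sequence[Sequence[HalfSessionScore]],
) -> list[HalfSessionScore]:
    """Group curve: unweighted mean across subjects of per-subject half-session
    means (NaN entries excluded per half-session)."""
    if not per_subject:
        raise ValueError("no subjects")
    by_hs: dict[int, list[HalfSessionScore]] = {}
    for scores in per_subject:
        for s in scores:
            by_hs.setdefault(s.half_session, []).append(s)
    out = []
    for hs in sorted(by_hs):
        entries = [s for s in by_hs[hs] if np.isfinite(s.mean_diff)]
        if not entries:
            template = by_hs[hs][0]
            out.append(HalfSessionScore(hs, float("nan"), float("nan"), float("nan"),
                                        template.is_transfer, 0))
            continue
        out.append(
            HalfSessionScore(
                half_session=hs,
                mean_diff=float(np.mean([s.mean_diff for s in entries])),
                mean_target=float(np.mean([s.mean_target for s in entries])),
                mean_control=float(np.mean([s.mean_control for s in entries])),
                is_transfer=entries[0].is_transfer,
                n_blocks=int(np.mean([s.n_blocks for s in entries])),
            )
        )
    return out


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with the two-sided p from the t transform
    (n - 2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise InsufficientDataError("need at least 3 points for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("undefined correlation: zero variance")
    res = scipy.stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


MIN_CURVE_POINTS = 3


def learning_curve(
    scores: Sequence[HalfSessionScore], channel: Channel = "diff"
) -> LearningCurveResult:
    """Learning curve over feedback half-sessions.

    Correlates the per-half-session means of ``channel`` with the
    half-session number and fits a linear slope; also reports the target and
    control channel correlations and the between-curve (target vs control)
    correlation.  Transfer half-sessions are excluded; fewer than 3 usable
    points raise InsufficientDataError (e.g. the 4 transfer points of an
    8-session course are reported descriptively, not correlated).
    """
    fb = [
        s for s in scores
        if not s.is_transfer and np.isfinite(s.mean_diff) and s.n_blocks > 0
    ]
    if len(fb) < MIN_CURVE_POINTS:
        raise InsufficientDataError(
            f"only {len(fb)} feedback half-sessions; need >= {MIN_CURVE_POINTS}"
        )
    x = np.array([s.half_session for s in fb], dtype=float)
    ys = {
        "diff": np.array([s.mean_diff for s in fb]),
        "target": np.array([s.mean_target for s in fb]),
        "control": np.array([s.mean_control for s in fb]),
    }
    r_main, p_main = pearson_r(x, ys[channel])
    slope = float(np.polyfit(x, ys[channel], 1)[0])

    def _safe_r(a: np.ndarray, b: np.ndarray) -> float:
        if np.std(a) == 0 or np.std(b) == 0:
            return float("nan")
        return float(scipy.stats.pearsonr(a, b).statistic)

    return LearningCurveResult(
        r_diff=r_main if channel == "diff" else _safe_r(x, ys["diff"]),
        p_diff=p_main,
        slope=slope,
        r_target=r_main if channel == "target" else _safe_r(x, ys["target"]),
        r_control=r_main if channel == "control" else _safe_r(x, ys["control"]),
        r_between_curves=_safe_r(ys["target"], ys["control"]),
        n_points=len(fb),
        channel=channel,
    )
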