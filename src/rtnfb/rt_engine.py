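"""Streaming re-implementation of the online feedback computation.

Per volume: percent signal change (PSC) of the target and control ROI against
a fixed per-run baseline, target-minus-control differencing (common-mode
rejection of global artifacts), and min/max normalization of the difference
over a sliding window spanning the previous minute.  The resulting score in
[0, 1] drives the feedback display (disk size); in transfer runs the score is
still computed and logged but never displayed.

The PSC baseline is taken as the per-ROI mean of the non-discarded volumes of
the run's first down-regulation block (the paradigm's rest condition); a
running-mean alternative is available for sensitivity checks.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Literal

import numpy as np

from .paradigm import Condition, RunSpec

__all__ = [
    "StreamState",
    "FeedbackSample",
    "NotReadyError",
    "psc",
    "diff_score",
    "normalize_minmax",
    "init_state",
    "step",
    "run_stream",
]

#: Length of the normalization window, seconds ("the previous minute").
WINDOW_S = 60.0

#: Degenerate-range threshold for min/max normalization.
RANGE_EPS = 1e-9

BaselineMode = Literal["first_down_block", "running_mean"]


class NotReadyError(RuntimeError):
    """step() called before the PSC baselines are initialized."""


@dataclass
class StreamState:
    """Mutable per-run state of the online engine."""

    run: RunSpec
    baseline_mode: BaselineMode = "first_down_block"
    baseline_target: float | None = None
    baseline_control: float | None = None
    #: (time_s, diff) pairs no older than WINDOW_S.
    window: deque = field(default_factory=deque)
    volumes_seen: int = 0
    next_volume: int = 0
    # running sums for baseline_mode == "running_mean"
    _sum_target: float = 0.0
    _sum_control: float = 0.0

    @property
    def ready(self) -> bool:
        return self.baseline_target is not None and self.baseline_control is not None


@dataclass(frozen=True)
class FeedbackSample:
    """Online result for one volume."""

    volume: int
    time_s: float
    psc_target: float
    psc_control: float
    diff: float
    score: float
    displayed: bool


def psc(raw: float, baseline: float) -> float:
    """Percent signal change: 100 * (raw - baseline) / baseline."""
    if baseline <= 0:
        raise ValueError(f"baseline must be > 0, got {baseline}")
    return 100.0 * (raw - baseline) / baseline


def diff_score(psc_target: float, psc_control: float) -> float:
    """Target-minus-control PSC difference (common-mode rejection)."""
    return psc_target - psc_control


def normalize_minmax(current: float, window: Iterable[float], eps: float = RANGE_EPS) -> float:
    """Normalize ``current`` to [0, 1] by the min/max of the window including
    the current value; a degenerate range maps to the neutral 0.5."""
    lo = hi = current
    for v in window:
        if v < lo:
            lo = v
        if v > hi:
            hi = v
    if hi - lo < eps:
        return 0.5
    return min(1.0, max(0.0, (current - lo) / (hi - lo)))


def _first_down_block_indices(run: RunSpec) -> np.ndarray:
    for b in run.blocks:
        if b.condition is Condition.DOWN:
            i0 = int(round(b.onset_s / run.tr_s))
            i1 = int(round(b.end_s / run.tr_s))
            idx = np.arange(max(i0, run.n_discard), min(i1, run.n_volumes))
            if idx.size == 0:
                raise ValueError("first down block fully discarded; cannot set baseline")
            return idx
    raise ValueError("run has no down block; cannot set baseline")


def init_state(
    run: RunSpec,
    target: np.ndarray | None = None,
    control: np.ndarray | None = None,
    baseline_mode: BaselineMode = "first_down_block",
) -> StreamState:
    """Create the engine state for a run.

    With ``baseline_mode='first_down_block'`` the per-ROI baselines are the
    means of the non-discarded volumes of the run's first down block, so the
    full series (or at least that block) must be supplied here; with
    ``'running_mean'`` baselines accrue online and no series is needed.
    """
    state = StreamState(run=run, baseline_mode=baseline_mode)
    if baseline_mode == "first_down_block":
        if target is None or control is None:
            raise ValueError("first_down_block baseline requires the series")
        idx = _first_down_block_indices(run)
        if idx[-1] >= len(target) or idx[-1] >= len(control):
            raise ValueError("series too short to cover the first down block")
        bt = float(np.mean(np.asarray(target, dtype=float)[idx]))
        bc = float(np.mean(np.asarray(control, dtype=float)[idx]))
        if bt <= 0 or bc <= 0:
            raise ValueError("baselines must be positive")
        state.baseline_target = bt
        state.baseline_control = bc
    elif baseline_mode != "running_mean":
        raise ValueError(f"unknown baseline_mode: {baseline_mode}")
    state.next_volume = run.n_discard
    return state


def step(
    state: StreamState, target_raw: float, control_raw: float, run: RunSpec
) -> tuple[StreamState, FeedbackSample]:
    """Process one volume: PSC -> diff -> windowed min/max score.

    Appends the diff to the sliding window, evicting values 60 s old or
    older, and returns the per-volume FeedbackSample.  Work per step is
    bounded by the window capacity (60 / TR values).
    """
    if state.baseline_mode == "running_mean":
        state._sum_target += float(target_raw)
        state._sum_control += float(control_raw)
        n = state.volumes_seen + 1
        state.baseline_target = state._sum_target / n
        state.baseline_control = state._sum_control / n
    if not state.ready:
        raise NotReadyError("baselines not initialized; caller must buffer")
    volume = state.next_volume
    t_now = volume * run.tr_s
    p_t = psc(float(target_raw), state.baseline_target)
    p_c = psc(float(control_raw), state.baseline_control)
    d = diff_score(p_t, p_c)
    # keep entries strictly younger than 60 s; the current value joins them
    while state.window and state.window[0][0] <= t_now - WINDOW_S:
        state.window.popleft()
    state.window.append((t_now, d))
    score = normalize_minmax(d, (v for _, v in state.window))
    state.volumes_seen += 1
    state.next_volume = volume + 1
    sample = FeedbackSample(
        volume=volume,
        time_s=t_now,
        psc_target=p_t,
        psc_control=p_c,
        diff=d,
        score=score,
        displayed=run.feedback,
    )
    return state, sample


def run_stream(
    run: RunSpec,
    target: np.ndarray,
    control: np.ndarray,
    baseline_mode: BaselineMode = "first_down_block",
) -> list[FeedbackSample]:
    """Batch replay of the online engine over a full run.

    Emits one FeedbackSample per non-discarded volume (volumes
    ``n_discard .. n_volumes - 1``).  Exactly equivalent to composing
    :func:`step` volume by volume.
    """
    target = np.asarray(target, dtype=float)
    control = np.asarray(control, dtype=float)
    if len(target) != run.n_volumes or len(control) != run.n_volumes:
        raise ValueError(
            f"series length {len(target)}/{len(control)} != n_volumes {run.n_volumes}"
        )
    if run.n_volumes == 0:
        raise ValueError("empty series")
    state = init_state(run, target, control, baseline_mode=baseline_mode)
    samples: list[FeedbackSample] = []
    for v in range(run.n_discard, run.n_volumes):
        state, sample = step(state, target[v], control[v], run)
        samples.append(sample)
    return samples
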