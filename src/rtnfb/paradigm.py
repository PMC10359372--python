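"""Block-design paradigm and neurofeedback course scheduling.

The training paradigm alternates down-regulation (20 s) and up-regulation
(40 s) blocks; one trial is a 20 s down block followed by a 40 s up block
(60 s total).  Each scanning session has two runs: run 1 with 15 trials
(15 min, 900 volumes at TR = 1 s) and run 2 with 10 trials (10 min,
600 volumes).  Run 1 always provides the feedback display; in every even
session run 2 is a transfer run — same regulation paradigm but no feedback —
testing whether the regulation skill generalizes.  A standard course has 8
sessions, i.e. 16 half-sessions: 12 with feedback and 4 transfer.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterator

import numpy as np

__all__ = [
    "Condition",
    "BlockSpec",
    "RunSpec",
    "SessionSpec",
    "CourseSpec",
    "ConsortFlow",
    "build_block_sequence",
    "build_run",
    "build_course",
    "condition_labels",
    "DOWN_DURATION_S",
    "UP_DURATION_S",
    "TRIAL_DURATION_S",
    "N_TRIALS_RUN1",
    "N_TRIALS_RUN2",
    "DEFAULT_TR_S",
    "N_DISCARD_ONLINE",
    "N_DISCARD_OFFLINE",
]

#: Block durations in seconds: down-regulation 20 s, up-regulation 40 s.
DOWN_DURATION_S = 20.0
UP_DURATION_S = 40.0
TRIAL_DURATION_S = DOWN_DURATION_S + UP_DURATION_S

#: Trials per run: the first run of a session has 15, the second 10.
N_TRIALS_RUN1 = 15
N_TRIALS_RUN2 = 10

#: Repetition time of the EPI sequence, seconds.
DEFAULT_TR_S = 1.0

#: Initial volumes dropped for T1 saturation: 5 in the online engine,
#: 3 in the offline analysis.
N_DISCARD_ONLINE = 5
N_DISCARD_OFFLINE = 3

DEFAULT_N_SESSIONS = 8


class Condition(str, Enum):
    """Regulation condition of a block."""

    DOWN = "down"
    UP = "up"


@dataclass(frozen=True)
class BlockSpec:
    """One regulation block: condition, onset and duration in seconds.

    Onsets are 0-based; a block occupies the half-open interval
    [onset_s, onset_s + duration_s).
    """

    condition: Condition
    onset_s: float
    duration_s: float

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError(f"block onset must be >= 0, got {self.onset_s}")
        if self.duration_s <= 0:
            raise ValueError(f"block duration must be > 0, got {self.duration_s}")

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class RunSpec:
    """One run (half-session): trial count, feedback flag and block layout."""

    run_index: int
    n_trials: int
    feedback: bool
    tr_s: float = DEFAULT_TR_S
    n_discard: int = N_DISCARD_ONLINE
    blocks: tuple[BlockSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.run_index not in (1, 2):
            raise ValueError(f"run_index must be 1 or 2, got {self.run_index}")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.n_discard < 0:
            raise ValueError("n_discard must be >= 0")

    @property
    def duration_s(self) -> float:
        return self.n_trials * TRIAL_DURATION_S

    @property
    def n_volumes(self) -> int:
        nv = self.duration_s / self.tr_s
        if abs(nv - round(nv)) > 1e-9:
            raise ValueError(
                f"run duration {self.duration_s}s is not a multiple of TR {self.tr_s}s"
            )
        return int(round(nv))


@dataclass(frozen=True)
class SessionSpec:
    """One scanning session: two runs; run 2 is a transfer run in even sessions."""

    session_index: int
    runs: tuple[RunSpec, RunSpec]


@dataclass(frozen=True)
class CourseSpec:
    """A full neurofeedback course: ordered sessions and half-session numbering."""

    n_sessions: int
    sessions: tuple[SessionSpec, ...]

    def half_session_index(self, session_index: int, run_index: int) -> int:
        """Consecutive half-session number, 1-based and chronological."""
        if not 1 <= session_index <= self.n_sessions:
            raise ValueError(f"session_index out of range: {session_index}")
        if run_index not in (1, 2):
            raise ValueError(f"run_index must be 1 or 2, got {run_index}")
        return (session_index - 1) * 2 + run_index

    def iter_runs(self) -> Iterator[tuple[int, int, RunSpec]]:
        """Yield (half_session, session_index, RunSpec) in chronological order."""
        for session in self.sessions:
            for run in session.runs:
                yield (
                    self.half_session_index(session.session_index, run.run_index),
                    session.session_index,
                    run,
                )

    @property
    def n_feedback_runs(self) -> int:
        return sum(1 for _, _, run in self.iter_runs() if run.feedback)

    @property
    def n_transfer_runs(self) -> int:
        return sum(1 for _, _, run in self.iter_runs() if not run.feedback)

    def is_transfer(self, half_session: int) -> bool:
        for hs, _, run in self.iter_runs():
            if hs == half_session:
                return not run.feedback
        raise ValueError(f"half_session out of range: {half_session}")


def build_block_sequence(
    n_trials: int, tr_s: float = DEFAULT_TR_S, up_first: bool = False
) -> tuple[BlockSpec, ...]:
    """Build the alternating block layout of a run.

    Each trial contributes one 20 s down block and one 40 s up block, down
    first by default (the down block acts as the regulation baseline).
    Onsets tile the run contiguously from 0: no gaps, no overlaps.

    Parameters
    ----------
    n_trials
        Number of trials (>= 0).
    tr_s
        Repetition time in seconds; block boundaries must fall on the TR grid.
    up_first
        Reverse the within-trial order (sensitivity checks only).
    """
    if not isinstance(n_trials, (int, np.integer)) or isinstance(n_trials, bool):
        raise ValueError(f"n_trials must be an integer, got {n_trials!r}")
    if n_trials < 0:
        raise ValueError(f"n_trials must be >= 0, got {n_trials}")
    order = (
        (Condition.UP, UP_DURATION_S), (Condition.DOWN, DOWN_DURATION_S)
    ) if up_first else (
        (Condition.DOWN, DOWN_DURATION_S), (Condition.UP, UP_DURATION_S)
    )
    blocks: list[BlockSpec] = []
    onset = 0.0
    for _ in range(int(n_trials)):
        for condition, duration in order:
            blocks.append(BlockSpec(condition, onset, duration))
            onset += duration
    return tuple(blocks)


def build_run(
    run_index: int,
    feedback: bool = True,
    tr_s: float = DEFAULT_TR_S,
    n_discard: int = N_DISCARD_ONLINE,
    up_first: bool = False,
) -> RunSpec:
    """Build the canonical RunSpec for run 1 (15 trials) or run 2 (10 trials)."""
    n_trials = {1: N_TRIALS_RUN1, 2: N_TRIALS_RUN2}.get(run_index)
    if n_trials is None:
        raise ValueError(f"run_index must be 1 or 2, got {run_index}")
    return RunSpec(
        run_index=run_index,
        n_trials=n_trials,
        feedback=feedback,
        tr_s=tr_s,
        n_discard=n_discard,
        blocks=build_block_sequence(n_trials, tr_s, up_first=up_first),
    )


def build_course(
    n_sessions: int = DEFAULT_N_SESSIONS,
    tr_s: float = DEFAULT_TR_S,
    n_discard: int = N_DISCARD_ONLINE,
    up_first: bool = False,
) -> CourseSpec:
    """Build a full course: run 1 always feedback; run 2 transfer in even sessions.

    For ``n_sessions`` sessions the course has ``2 * n_sessions`` half-sessions
    of which ``n_sessions // 2`` are transfer runs.
    """
    if not isinstance(n_sessions, (int, np.integer)) or isinstance(n_sessions, bool):
        raise ValueError(f"n_sessions must be an integer, got {n_sessions!r}")
    if n_sessions < 1:
        raise ValueError(f"n_sessions must be >= 1, got {n_sessions}")
    sessions = []
    for s in range(1, int(n_sessions) + 1):
        run1 = build_run(1, feedback=True, tr_s=tr_s, n_discard=n_discard, up_first=up_first)
        run2 = build_run(
            2, feedback=(s % 2 == 1), tr_s=tr_s, n_discard=n_discard, up_first=up_first
        )
        sessions.append(SessionSpec(session_index=s, runs=(run1, run2)))
    return CourseSpec(n_sessions=int(n_sessions), sessions=tuple(sessions))


def condition_labels(run: RunSpec) -> list[Condition]:
    """Volume-wise condition labels: label of volume v is the condition of the
    block containing time ``v * tr_s``.  Length equals ``run.n_volumes``."""
    labels: list[Condition] = []
    blocks = run.blocks
    b = 0
    for v in range(run.n_volumes):
        t = v * run.tr_s
        while b < len(blocks) - 1 and t >= blocks[b].end_s:
            b += 1
        labels.append(blocks[b].condition)
    return labels


@dataclass(frozen=True)
class ConsortFlow:
    """Participant-flow bookkeeping for the trial.

    Of 64 screened candidates, 13 declined before the interventions and 26
    failed the EEG self-regulation screening, leaving 25 allocated across the
    three arms (12 fMRI neurofeedback, 8 CBT, 5 EEG neurofeedback; the EEG
    arm was stopped and discarded).  Four records were excluded for technical
    issues, giving 8 analyzed per remaining group, of whom 6 per group
    completed the full course.
    """

    screened: int = 64
    declined: int = 13
    failed_screening: int = 26
    arm_nfb: int = 12
    arm_cbt: int = 8
    arm_eeg_discarded: int = 5
    technical_exclusions: int = 4
    analyzed_per_group: int = 8
    completed_per_group: int = 6

    @property
    def allocated(self) -> int:
        return self.screened - self.declined - self.failed_screening

    def validate(self) -> None:
        if self.allocated != self.arm_nfb + self.arm_cbt + self.arm_eeg_discarded:
            raise ValueError("arm counts do not sum to the allocated total")
        if self.arm_nfb - self.technical_exclusions != self.analyzed_per_group:
            raise ValueError("analyzed count inconsistent with exclusions")
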