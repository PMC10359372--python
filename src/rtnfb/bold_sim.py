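"""Synthetic two-ROI BOLD generator with a programmable learning effect,
plus a two-group three-timepoint clinical score generator.

The BOLD model
--------------
For half-session ``h`` of a course, the target-ROI regulation amplitude is

    a(h) = a0 + beta * (h - 1)        [percent signal change]

i.e. regulation skill grows linearly over the course.  Volumes are generated
around a baseline intensity ``B`` as

    target(t)  = B * (1 + a(h)/100 * x(t) + g(t) + d(t) + e_T(t))
    control(t) = B * (1 + leak * a(h)/100 * x(t) + gc * g(t) + d(t) + e_C(t))

where ``x(t)`` is the stair-step regressor (the up/down boxcar delayed by the
hemodynamic lag and rising/falling through a small number of equal steps),
``g`` a smooth global fluctuation shared by both ROIs (inducing the
target-control correlation seen in real data), ``d`` a zero-mean linear drift,
and ``e`` independent AR(1) noise per ROI.  ``leak`` models the fraction of
the regulation effect that spills into the control ROI because the control
region shares non-specific activation with the target.

The clinical model
------------------
Depression scores for two groups (NFB, CBT) at three timepoints (pre, mid,
post): a subject-specific baseline plus a group-specific linear decline per
assessment plus residual noise.  MADRS is integer-valued on 0-60; BDI and
ZSRDS are generated analogously on their instrument ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .paradigm import BlockSpec, Condition, CourseSpec, RunSpec

__all__ = [
    "SimParams",
    "SimulatedRun",
    "ClinicalSimParams",
    "stair_step_regressor",
    "simulate_run",
    "simulate_course",
    "simulate_clinical",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of the BOLD generator.

    All *_pct parameters are percent of the baseline signal.  ``amp0_pct`` is
    the regulation amplitude at half-session 1 and ``learning_slope_pct`` its
    increment per half-session.
    """

    baseline_signal: float = 1000.0
    amp0_pct: float = 0.5
    learning_slope_pct: float = 0.15
    hrf_delay_s: float = 5.0
    hrf_rise_steps: int = 2
    noise_sd_pct: float = 0.5
    drift_pct_per_min: float = 0.2
    global_amp_pct: float = 0.4
    global_gain_control: float = 1.0
    control_leak: float = 0.15
    ar1: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_signal <= 0:
            raise ValueError("baseline_signal must be > 0")
        for name in ("amp0_pct", "learning_slope_pct", "noise_sd_pct",
                     "drift_pct_per_min", "global_amp_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 <= self.control_leak <= 1:
            raise ValueError("control_leak must be in [0, 1]")
        if not 0 <= self.global_gain_control <= 1:
            raise ValueError("global_gain_control must be in [0, 1]")
        if self.hrf_rise_steps < 1:
            raise ValueError("hrf_rise_steps must be >= 1")
        if self.hrf_delay_s < 0:
            raise ValueError("hrf_delay_s must be >= 0")
        if not 0 <= self.ar1 < 1:
            raise ValueError("ar1 must be in [0, 1)")


@dataclass(frozen=True)
class SimulatedRun:
    """One simulated half-session: both ROI series and the programmed truth."""

    target: np.ndarray
    control: np.ndarray
    truth_amp_pct: float
    half_session: int
    run_spec: RunSpec

    def __post_init__(self) -> None:
        if len(self.target) != self.run_spec.n_volumes or len(self.control) != self.run_spec.n_volumes:
            raise ValueError("series length must equal run_spec.n_volumes")


def programmed_amplitude(params: SimParams, half_session: int) -> float:
    """Target-ROI regulation amplitude a0 + beta*(h-1), percent."""
    if half_session < 1:
        raise ValueError("half_session must be >= 1")
    return params.amp0_pct + params.learning_slope_pct * (half_session - 1)


def stair_step_regressor(
    blocks: tuple[BlockSpec, ...] | list[BlockSpec],
    tr_s: float,
    delay_s: float,
    rise_steps: int,
) -> np.ndarray:
    """Stair-step hemodynamic model of the up/down paradigm.

    The up=1 / down=0 boxcar, sampled per volume, is delayed by ``delay_s``
    and its transitions are spread over ``rise_steps`` equal piecewise-constant
    steps (rise_steps = 1 reduces to a pure delayed boxcar).  Values in [0, 1].
    """
    if rise_steps < 1:
        raise ValueError("rise_steps must be >= 1")
    if delay_s < 0:
        raise ValueError("delay_s must be >= 0")
    duration = sum(b.duration_s for b in blocks)
    n = int(round(duration / tr_s))
    if n == 0:
        return np.zeros(0)
    if delay_s >= duration:
        raise ValueError(f"delay {delay_s}s exceeds run duration {duration}s")
    boxcar = np.zeros(n)
    for b in blocks:
        if b.condition is Condition.UP:
            i0 = int(round(b.onset_s / tr_s))
            i1 = int(round(b.end_s / tr_s))
            boxcar[i0:min(i1, n)] = 1.0
    delay_vol = int(round(delay_s / tr_s))
    shifted = np.zeros(n)
    if delay_vol < n:
        shifted[delay_vol:] = boxcar[: n - delay_vol]
    kernel = np.full(rise_steps, 1.0 / rise_steps)
    return np.convolve(shifted, kernel)[:n]


def _run_rng(params: SimParams, subject_seed: int, half_session: int) -> np.random.Generator:
    ss = np.random.SeedSequence(
        entropy=[int(params.seed) & 0xFFFFFFFF, int(subject_seed) & 0xFFFFFFFF,
                 int(half_session)]
    )
    return np.random.default_rng(ss)


def _smooth_global(rng: np.random.Generator, n: int, tr_s: float, sd: float) -> np.ndarray:
    """Shared global fluctuation: white noise smoothed with a 10 s moving
    average, rescaled to the requested SD (zero mean)."""
    raw = rng.standard_normal(n)
    w = max(1, int(round(10.0 / tr_s)))
    g = np.convolve(raw, np.full(w, 1.0 / w), mode="same")
    g -= g.mean()
    s = g.std()
    if s > 0 and sd > 0:
        g *= sd / s
    else:
        g[:] = 0.0
    return g


def _ar1_noise(rng: np.random.Generator, n: int, sd: float, phi: float) -> np.ndarray:
    """AR(1) noise with marginal SD ``sd`` (approximates BOLD autocorrelation)."""
    innov = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    if phi == 0:
        return sd * innov
    series = lfilter([1.0], [1.0, -phi], innov * np.sqrt(1.0 - phi**2))
    return sd * series


def simulate_run(
    params: SimParams,
    run_spec: RunSpec,
    half_session: int,
    subject_seed: int = 0,
) -> SimulatedRun:
    """Simulate one half-session of two-ROI BOLD data.

    Reproducible: identical (params, run_spec, half_session, subject_seed)
    give bitwise-identical series.
    """
    rng = _run_rng(params, subject_seed, half_session)
    n = run_spec.n_volumes
    tr = run_spec.tr_s
    reg = stair_step_regressor(
        run_spec.blocks, tr, params.hrf_delay_s, params.hrf_rise_steps
    )
    amp = programmed_amplitude(params, half_session)

    g = _smooth_global(rng, n, tr, params.global_amp_pct / 100.0)
    # Per-run drift slope drawn with random sign; zero-mean within the run.
    drift_slope = rng.normal(0.0, params.drift_pct_per_min) / 100.0 / 60.0
    t = np.arange(n) * tr
    d = drift_slope * (t - t.mean()) if params.drift_pct_per_min > 0 else np.zeros(n)
    e_t = _ar1_noise(rng, n, params.noise_sd_pct / 100.0, params.ar1)
    e_c = _ar1_noise(rng, n, params.noise_sd_pct / 100.0, params.ar1)

    b = params.baseline_signal
    target = b * (1.0 + amp / 100.0 * reg + g + d + e_t)
    control = b * (
        1.0
        + params.control_leak * amp / 100.0 * reg
        + params.global_gain_control * g
        + d
        + e_c
    )
    return SimulatedRun(
        target=target,
        control=control,
        truth_amp_pct=amp,
        half_session=half_session,
        run_spec=run_spec,
    )


def simulate_course(
    params: SimParams,
    course: CourseSpec,
    n_subjects: int,
    seed: int | None = None,
) -> dict[int, list[SimulatedRun]]:
    """Simulate a cohort: one SimulatedRun per (subject, half-session).

    Returns a mapping subject index (1-based) -> runs in chronological order.
    Per-subject seeds are derived deterministically from the master seed.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = params.seed if seed is None else seed
    p = replace(params, seed=int(master))
    subject_seeds = np.random.SeedSequence(int(master) & 0xFFFFFFFF).generate_state(
        n_subjects
    )
    cohort: dict[int, list[SimulatedRun]] = {}
    for s in range(1, n_subjects + 1):
        runs = [
            simulate_run(p, run, half_session=hs, subject_seed=int(subject_seeds[s - 1]))
            for hs, _, run in course.iter_runs()
        ]
        cohort[s] = runs
    return cohort


#: Instrument score ranges (min, max) used for clipping.
_SCALE_RANGES = {"madrs": (0, 60), "bdi": (0, 63), "zsrds": (20, 80)}

#: Secondary-scale generator settings: group baseline means (NFB, CBT),
#: between-subject SD, and decline per assessment (NFB, CBT).  Chosen to
#: emulate a strong clinician-rated improvement, a weaker self-report (BDI)
#: improvement and an essentially flat ZSRDS.
_SECONDARY_DEFAULTS = {
    "bdi": {"mean": (27.4, 24.1), "sd": 10.8, "decline": (4.0, 5.0)},
    "zsrds": {"mean": (54.3, 48.3), "sd": 5.2, "decline": (1.5, 1.5)},
}

TIMEPOINTS = ("pre", "mid", "post")
GROUPS = ("NFB", "CBT")


@dataclass(frozen=True)
class ClinicalSimParams:
    """Parameters of the clinical score generator (MADRS anchors; BDI and
    ZSRDS follow with instrument-specific defaults).

    ``subject_sd`` (between-subject SD of the latent baseline) defaults to
    sqrt(baseline_sd^2 - residual_sd^2) so that the observed baseline SD
    matches ``baseline_sd``.
    """

    n_per_group: int = 8
    baseline_mean: float = 27.8
    baseline_sd: float = 3.1
    decline_nfb: float = 5.0
    decline_cbt: float = 7.0
    subject_sd: float | None = None
    residual_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for name in ("baseline_sd", "residual_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.subject_sd is not None and self.subject_sd < 0:
            raise ValueError("subject_sd must be >= 0")

    @property
    def effective_subject_sd(self) -> float:
        if self.subject_sd is not None:
            return self.subject_sd
        return float(np.sqrt(max(self.baseline_sd**2 - self.residual_sd**2, 0.0)))


def simulate_clinical(params: ClinicalSimParams) -> pd.DataFrame:
    """Generate a clinical score table.

    One row per subject x timepoint with columns
    ``subject_id, group, time, madrs, bdi, zsrds``.  score(t) =
    subject baseline - group decline * t + residual, integer-rounded and
    clipped to the instrument range.
    """
    rng = np.random.default_rng(np.random.SeedSequence(int(params.seed) & 0xFFFFFFFF))
    rows = []
    declines_madrs = {"NFB": params.decline_nfb, "CBT": params.decline_cbt}
    for group in GROUPS:
        for i in range(1, params.n_per_group + 1):
            subject_id = f"{group.lower()}{i:02d}"
            base_madrs = rng.normal(params.baseline_mean, params.effective_subject_sd)
            base_sec = {
                scale: rng.normal(
                    cfg["mean"][GROUPS.index(group)],
                    cfg["sd"],
                )
                for scale, cfg in _SECONDARY_DEFAULTS.items()
            }
            for t_idx, time in enumerate(TIMEPOINTS):
                scores = {
                    "madrs": base_madrs
                    - declines_madrs[group] * t_idx
                    + rng.normal(0.0, params.residual_sd)
                }
                for scale, cfg in _SECONDARY_DEFAULTS.items():
                    scores[scale] = (
                        base_sec[scale]
                        - cfg["decline"][GROUPS.index(group)] * t_idx
                        + rng.normal(0.0, params.residual_sd)
                    )
                row = {"subject_id": subject_id, "group": group, "time": time}
                for scale, value in scores.items():
                    lo, hi = _SCALE_RANGES[scale]
                    row[scale] = int(np.clip(round(value), lo, hi))
                rows.append(row)
    return pd.DataFrame(rows)
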