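# Methods

This note documents the models implemented in `rtnfb`, their assumptions,
the defaults and why, and the design decisions taken where the protocol
leaves the computation underdetermined. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Paradigm model

A *trial* is a 20 s down-regulation block followed by a 40 s up-regulation
block; blocks tile each run contiguously from t = 0 with half-open
intervals `[onset, onset + duration)`. Run 1 has 15 trials (900 s, 900
volumes at TR = 1 s), run 2 has 10 trials (600 s). A course has 8 sessions
of two runs; run 1 always carries the feedback display, run 2 is a
transfer run (paradigm without display) in even sessions. Half-sessions
are numbered chronologically 1–16.

Decisions:

- **Within-trial order.** The protocol lists the two conditions without
  fixing their order; we put the down block first because it serves as the
  local regulation baseline of the following up block. An `up_first` flag
  exists for sensitivity checks.
- **Discarded volumes.** The online engine drops the first 5 volumes
  (T1 saturation at the scanner); the offline analysis drops 3. Both are
  configuration parameters (`n_discard_online` / `n_discard_offline`)
  because the original processing used different values in the two stages
  and published statistics could correspond to either.

## Synthetic BOLD generator

Per half-session `h`, the target-ROI regulation amplitude (percent of
baseline) is

    a(h) = a0 + beta * (h − 1),     defaults a0 = 0.5, beta = 0.15

and the two channels are generated as

    target(t)  = B · (1 + a(h)/100 · x(t) + g(t) + d(t) + e_T(t))
    control(t) = B · (1 + leak · a(h)/100 · x(t) + gc · g(t) + d(t) + e_C(t))

with `B = 1000` a.u. and:

- **x(t), stair-step hemodynamic model** — the up/down boxcar delayed by
  `hrf_delay_s` (default 5 s) with transitions spread over
  `hrf_rise_steps` (default 2) equal piecewise-constant steps. This is the
  same family of regressor the scanner-side software uses online, not a
  canonical double-gamma HRF.
- **g(t), shared global fluctuation** — white noise smoothed with a 10 s
  moving average, rescaled to SD `global_amp_pct/100` (default 0.4 %),
  entering the control channel with gain `global_gain_control` (default 1).
  It exists so that target-minus-control subtraction demonstrably removes
  common-mode artifacts, and it is what makes the two channels correlated,
  as ROI pairs in real recordings are.
- **leak** (default 0.15) — fraction of the regulation effect spilling
  into the control ROI, since a hemisphere-sized control region shares
  non-specific activation with the target. It makes the diff curve's slope
  `(1 − leak)·beta` rather than `beta`.
- **d(t), drift** — linear within run, zero-mean, slope drawn per run from
  N(0, `drift_pct_per_min` = 0.2 %/min): slow scanner drift has no
  preferred sign. Zero-mean-within-run matches the offline linear
  detrending stage.
- **e(t), noise** — independent per ROI, AR(1) with coefficient 0.3
  (a coarse stand-in for BOLD autocorrelation) and marginal SD
  `noise_sd_pct/100` (default 0.5 %).

Reproducibility: every run's RNG is seeded from
(master seed, subject seed, half-session), so cohorts are bitwise
reproducible and subjects/half-sessions are independent streams.

What the generator does *not* emulate: physiological (cardiac/respiratory)
noise, motion and spin-history artifacts, spatial structure (except the
optional toy NIfTI export), nonlinear HRF saturation, and
between-subject variability in hemodynamics or learning rate (all subjects
share `a0`/`beta`). Passing tests therefore demonstrate the correctness and
calibration of the *computations* under a plausible signal model, not
performance on real recordings.

The generator's learning-effect defaults were chosen once so that a
6-subject cohort's group learning curve lies in the high-correlation
regime the protocol's designers reported for their cohort; this is an
illustrative operating point, not a claim about the original data.

## Clinical score generator

Per subject: a latent baseline ~ N(`baseline_mean` = 27.8,
`subject_sd`), with `subject_sd` defaulting to
sqrt(`baseline_sd`² − `residual_sd`²) so the observed baseline SD matches
`baseline_sd` = 3.1; scores decline linearly per assessment
(NFB 5, CBT 7 MADRS points) plus residual noise (SD 2), integer-rounded
and clipped to the instrument range (MADRS 0–60). BDI and ZSRDS are
generated analogously with group-specific baseline means (27.4/24.1 and
54.3/48.3) and decline rates chosen to emulate the typical pattern of a
strong clinician-rated improvement, a weaker self-report improvement and
an essentially flat ZSRDS.

## Online feedback engine

PSC per ROI against a fixed per-run baseline; the baseline is the mean of
the non-discarded volumes of the run's *first down block* (the paradigm's
rest condition). The protocol does not define the PSC reference of the
original scanner software; a `running_mean` alternative is provided. The
target-minus-control difference is normalized by the min/max of a sliding
window spanning the previous 60 s *including* the current value; a value
exactly 60 s old has left the window, so the window holds at most
60/TR values. A window range below 1e-9 yields the neutral score 0.5
(disk at half size); values pushed outside [min, max] by floating point
are clipped rather than rejected. Transfer runs compute and log scores but
set `displayed = false`. The streaming `step` contract is O(window) work
per volume; the batch `run_stream` is exactly the composition of steps.

## Offline learning-curve analysis

Series are linearly detrended (mean restored, so PSC denominators stay
valid). Per trial, the up and preceding down windows are shifted by
`lag_s` (default 5 s, matching a typical hemodynamic delay; the original
processing does not state its lag) and intersected with the analyzable
run; trials with an empty window are dropped. The block score is
`100·(mean_up − mean_down)/ref` with `ref` the preceding down-block mean
(default) or the run mean; with the run-mean reference
`mean_diff = mean_target − mean_control` holds as an exact algebraic
identity. Half-session means keep feedback and transfer runs separate;
the group curve is the unweighted mean over subjects. The learning curve
is the Pearson r (two-sided p via the t transform, n − 2 df) and
least-squares slope of the feedback half-session means against
half-session number; fewer than 3 usable points (e.g. the 4 transfer
points of an 8-session course) is reported as insufficient for a
correlation rather than a number. Missing runs are reported as absent,
never imputed.

Numerical notes: the noise-free oracle identity (block scores equal the
programmed amplitude to 1e-6) holds with `detrend="none"`, lag matched to
the generator delay and a single rise step; with the defaults (2 rise
steps, detrending) the estimand is the programmed amplitude attenuated by
the stair-step transitions and the detrend projection, which is why the
parameter-recovery tests compare the recovered slope to the noise-free
limit of the declared analysis rather than to raw `beta`.

## Clinical statistics

Split-plot sums-of-squares decomposition: between-subject variation into
Group and Subjects-within-Groups, within-subject variation into Time,
Group × Time and the within-subject error, which is the error term for
both reported effects. `partial η² = SS_effect/(SS_effect + SS_error)`
with a 95 % CI from inverting the noncentral-F distribution in the
noncentrality parameter. Sphericity: Greenhouse–Geisser ε from the pooled
within-group covariance; corrected and uncorrected p are both reported
(with three levels the correction is mild, and under a spherical
generating model the uncorrected F is exactly F-distributed — the basis of
the type-I calibration test). Zero within-cell variance raises a
degenerate-design error. Incomplete subjects are dropped listwise per
scale, matching drop-out handling in a completers analysis. α = 0.05
two-sided; no correction across the three scales.

A consistency caveat worth knowing when comparing with published ANOVA
tables of this design: with N subjects in 2 groups and 3 timepoints the
Time effect has df = (2, 2·(N − 2)), and partial η² must satisfy
η² = F·df1/(F·df1 + df2); published tables do not always satisfy these
identities (reported df and η² can reflect a different software
convention), so the package asserts its own internal consistency and does
not attempt to force agreement with any particular printed table.

Tukey post hoc over timepoints uses the studentized range with
`q = |m_i − m_j|/sqrt(MS_error/N)` and the within-subject error df; the
unadjusted paired contrast p is reported alongside. Hedge's g defaults to
the independent-samples pooled-SD formula between the pre and post score
vectors (`df = n_a + n_b − 2`), because published within-group pre-post
effect sizes of this kind rarely state their formula; a paired
(change-score) variant is available via `paired=True` and generally gives
larger |g| because pre/post scores are positively correlated. Response is
a ≥ 50 % MADRS reduction; remission is post ≤ 10 (a conventional MADRS
threshold, exposed as a parameter).

## Problem sizes used in the bundled checks

Design sizes are the protocol's own (15/10-trial runs, 8-session courses,
6-subject cohorts, 8-per-group clinical tables). The Monte-Carlo checks
use 100 cohorts per arm for learning-curve recovery, 2000 null tables for
ANOVA calibration, 1000 random pairs for effect-size agreement and 10 000
random windows for the normalization scan; these sizes give binomial/
extreme-value resolution well inside the asserted bounds while keeping a
full test run under a minute of CPU.

## Known limitations

- The generator's global fluctuation and AR(1) noise are stationary;
  real BOLD noise is not.
- The online engine assumes a constant TR and gap-free volumes; dropped
  frames must be handled upstream.
- The GG ε pools covariance within groups; with 6 subjects per group the
  ε estimate is itself noisy.
- The learning-curve slope is a descriptive least-squares fit; no
  within-subject correlation structure is modeled across half-sessions.
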