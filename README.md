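# rtnfb

A tested, reusable implementation of the computational chain behind a
block-design real-time fMRI neurofeedback (rt-fMRI NFB) protocol for
depression, from the scanner-side feedback computation to the clinical
outcome statistics — exercisable end to end on a bundled synthetic data
generator, with no imaging downloads required.

## Who this is for

Researchers designing or re-analyzing rt-fMRI neurofeedback studies who need
a transparent, scriptable reference for each stage of such a pipeline:

1. **Paradigm / course scheduling** (`rtnfb.paradigm`) — alternating
   down- (20 s) and up-regulation (40 s) blocks; run 1 with 15 trials
   (900 volumes at TR = 1 s), run 2 with 10 trials (600 volumes); 8 sessions
   per course, with run 2 of every even session a *transfer* run (paradigm
   without feedback display) — 12 feedback and 4 transfer half-sessions.
2. **Synthetic BOLD + clinical generator** (`rtnfb.bold_sim`) — two-ROI
   (target / control) series with a regulation amplitude that grows linearly
   across half-sessions, a stair-step hemodynamic model, shared global
   fluctuations, drift and AR(1) noise; plus two-group (NFB / CBT),
   three-timepoint MADRS/BDI/ZSRDS score tables.
3. **Online feedback engine** (`rtnfb.rt_engine`) — per volume: percent
   signal change `PSC = 100·(S − B)/B` per ROI, target-minus-control
   difference `D = PSC_T − PSC_C`, then min/max normalization over the
   previous minute, `score = (D − min)/(max − min)` clipped to [0, 1]
   (0.5 on a degenerate window).
4. **Learning-curve analysis** (`rtnfb.learning_analysis`) — linear
   detrending, per-block up-vs-down PSC with a hemodynamic lag,
   per-half-session means for target, control and difference channels, and
   the Pearson correlation / slope of those means against half-session
   number (feedback and transfer half-sessions kept separate).
5. **Clinical statistics** (`rtnfb.clinical_stats`) — 2 × 3 mixed
   repeated-measures ANOVA (Time, Group × Time) with partial η², a
   noncentral-F confidence interval and Greenhouse–Geisser correction;
   Tukey post hoc over timepoints; Hedge's g with the small-sample
   correction `J = 1 − 3/(4·df − 1)`; Welch-t / chi-square baseline
   equivalence; response and remission counts.

## Worked example

```sh
rtnfb pipeline --seed 1 --out out/
rtnfb report --dir out/
```

prints (numbers produced by the run above):

```
course: 12 feedback + 4 transfer half-sessions
run 1: 900 volumes, 895 feedback samples
run 2: 600 volumes, 595 feedback samples
learning curve: r_diff=0.999 slope=0.1206 %/half-session (n=12)
MADRS Time: F(2,28)=99.9 p=1.803e-13 partial eta2=0.88
```

Reading: each run drops its first 5 volumes (T1 saturation) before the
online engine emits one score per volume. On this simulated 6-subject
cohort the target-minus-control regulation score rises almost perfectly
linearly over the 12 feedback half-sessions (r = 0.999), gaining ≈ 0.12
percentage points of signal change per half-session — the generator's
programmed learning effect, attenuated by the control-ROI leak and the
stair-step hemodynamic model. The clinical stage finds the strong
programmed Time effect on the MADRS score in the synthetic 8 + 8 subject
table. The same stages are available individually as `rtnfb simulate`,
`rtnfb feedback`, `rtnfb learn` and `rtnfb clinic`, and as plain library
calls.

## Scope notes

The package deliberately does not implement voxelwise GLM mapping,
smoothing/normalization/motion correction, EEG screening, scanner
connectivity or stimulus rendering. The study's real dataset (openneuro
`ds003770`, osf `qszd9`) can be substituted for the synthetic inputs via
the TSV/CSV interfaces but is not required or downloaded by anything here.
See `docs/methods.md` for the models, defaults and design decisions.
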