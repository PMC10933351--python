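# Methods

This note documents the models, decision rules and numerical choices behind
`blinkpipe`, in the order the pipeline applies them, and states what the
synthetic-data generator does and does not emulate.

## Eyeblink trace preprocessing

A trial is a 1.6 s eyelid-position time series (raw sensor units, larger =
more closed) with 500 ms of pre-CS baseline and ≥ 1000 ms after CS onset.
Latencies are milliseconds relative to CS onset; ms→sample mapping is
`floor(ms · rate / 1000)` and all analysis windows are closed intervals, so
window edges are deterministic at any sample rate (default 1 kHz; at 1 kHz
a millisecond is a sample, so the floor never loses an edge).

**Baseline alignment.** Each trial is shifted so the mean of its 500 ms
pre-CS window is zero. The operation is idempotent and shape-preserving.

**Validity filter.** Trials with significant pre-CS activity are invalid.
The activity statistic is the trial's maximum absolute deviation from its
own pre-CS median; the reference scale is the interquartile range (IQR) of
the pooled pre-CS samples of all trials in the session; a trial is rejected
when the statistic exceeds 7 × IQR. Neither the statistic nor the pooling
population is uniquely determined by the bare rule ("activity
exceeding 7 times the IQR"), so both are configurable: the statistic choice
(max |deviation from median|) is robust and scale-free, and the session
pooling gives every trial of a day the same reference. A per-trial IQR
variant is available (`iqr_scope="trial"`). Degenerate case: a zero IQR
(perfectly flat baselines) rejects any trial with nonzero activity, since
any deflection is then infinitely many IQRs. `factor=inf` disables the
filter. Invalid trials are excluded from everything downstream, including
the UR average.

**UR-referenced normalization.** Per mouse-day, the valid US-only trials
are averaged sample-wise over [US onset, US onset + 500 ms] and the maximum
of that average is the day's full-blink scale; every trace of the day is
divided by it. On the normalized scale 0 is the open eye, 1 a full blink,
and the day's averaged UR peaks at exactly 1 by construction. The 500 ms
averaging window captures the complete reflexive blink (rise ≲ 20 ms,
decay ≲ 300 ms) and is configurable. Fallbacks when a day has no valid
US-only trials: first the paired-trial post-US segments, then the previous
day's scale (each with a logged warning); a first day with no US-bearing
trials at all is an error. Because both the filter and the scale are ratios
of same-day quantities, the whole pipeline is scale-equivariant:
multiplying all raw traces of a day by any k > 0 changes nothing
downstream.

## CR detection and session outcomes

Only valid CS-only trials are scored — they show the full CR kinetic
profile without the reflexive UR on top — and the same criteria apply in
both ISI phases.

* **Peak**: maximum normalized closure in the closed window [100, 1000] ms
  (the NEC window); ties resolve to the earliest sample, so amplitude and
  peak latency come from a single argmax.
* **Onset**: the earliest post-CS sample above the onset threshold (0.05)
  from which the trace stays above threshold up to the peak ("sustained
  crossing"). A single-sample noise spike therefore cannot set the onset.
  The standard criteria leave onset undefined; this choice reproduces
  onset latencies in the 100–185 ms range on simulated data consistent
  with typical delay-conditioning kinetics.
* **CR**: peak amplitude > 0.1 and onset ∈ [50, 500] ms and peak ∈
  [100, 1000] ms (inclusive bounds; the rule is stated as "between",
  inclusivity is this package's documented reading).
* **Perfectly timed CR**: a CR whose peak lies within ISI ± 50 ms (250 ms
  phase) or ISI ± 100 ms (500 ms phase), bounds inclusive.

Per mouse-day the six outcomes are: CR probability (CRs / valid CS-only
trials); NEC over all valid CS-only trials; NEC over CR trials only (by
construction ≥ NEC-all on the same trial set); mean onset latency; mean
peak latency; and the percentage of perfectly timed CRs among CRs. Any
outcome with an empty denominator is missing, never zero.

**Endpoint analyses** pool CR trials per mouse over days 8–10 (ISI 250) or
18–20 (ISI 500). The perfectly-timed percentage is a trial-weighted pooled
ratio by default (a per-day-average variant exists behind a flag, since
pooling-vs-averaging is an open presentation choice). Group
summaries are mean ± t-based 95% CI over per-mouse values. Two further
analyses separate timing from response size: a mixed model of peak latency
on group with CR amplitude as a covariate (random intercept per mouse), and
an amplitude-matched re-analysis that keeps only CRs inside the enriched
group's amplitude IQR (computed from the data; a zero-width IQR degenerates
to a single amplitude with a warning).

## Motor assays

* **Rotarod**: latency to fall (s), 4 trials × 4 days, ceiling 300 s;
  values outside (0, 300] are rejected at construction.
* **ErasmusLadder**: runs arrive as time-ordered rung-touch sequences
  (paw, rung height). Only front-paw placements are scored; the first has
  no predecessor and is excluded. Under the default *landing* rule a
  transition is correct when the landing rung is high — the landing rung
  decides and step length never matters; touching a low rung is the
  misstep. A stricter *pair* rule (previous placement must also be high)
  is available; the usual wording admits both readings and the landing
  rule is the documented choice. Percent correct = 100 · correct /
  transitions, 42 runs × 5 days.
* **Balance beam**: crossing time (s) on 6 and 12 mm beams, 2 crossings
  each; beam widths outside {6, 12} are rejected.
* **Grip strength**: peak force, 2 trials × 4 days. Values are passed
  through verbatim in the unit the force gauge reports; the printed unit
  ("Newtons" at ~90–100) is physiologically implausible for mice and is
  most likely grams-force, so no unit conversion is attempted.

Table builders validate design cardinalities (warning on missingness,
which the mixed models tolerate; error on duplicate observations) and are
invariant to input row order.

## Mixed-effects comparison layer

Every group comparison is a linear mixed-effects model fitted by REML
(statsmodels `MixedLM`): fixed effects per assay (eyeblink outcomes:
group + day + group:day per ISI phase, phases always analyzed separately;
rotarod/ladder: group + day + group:day; beam: group + width + group:width;
grip: group), a random intercept per mouse always, plus a crossed random
intercept for trial (rotarod) or run (ladder) fitted as variance
components. Random slopes are not fitted. Categorical fixed effects use
sum-to-zero coding so each main-effect test is averaged over the other
factors rather than evaluated at a reference level.

Fixed terms are tested with Wald F statistics. Denominator degrees of
freedom use a containment (within/between) rule: a term whose design
columns are constant within mouse is tested against `n_mice − rank(between
design)`; all other terms against `n_obs − n_mice − rank(within design)`.
On balanced random-intercept designs this is the exact stratum df (e.g.
F(1, 26) for group and F(9, 234) for day on the 28-mouse × 10-day eyeblink
outcomes), and it degrades gracefully under missingness. Satterthwaite
approximation was considered and not implemented: statsmodels exposes no
machinery for it, and for the balanced random-intercept designs used here
the containment rule agrees with it to within rounding. The df method used
is recorded in every result.

Per-day post hoc contrasts are the adjusted group difference (standard −
enriched, i.e. second alphabetical level minus first) at each day, built
from design-row differences so they are correct under any coding, tested
against the between-mouse df, and corrected with Holm–Bonferroni step-down
(plain Bonferroni behind a flag, since the source alternates between the
two names). With a single day the contrast reduces to one two-group
comparison and the correction is the identity.

Model comparison reports log-likelihood, AIC and BIC from a parallel
maximum-likelihood fit (REML likelihoods are not comparable across fixed
effects), and a likelihood-ratio test against the largest strictly nested
competitor (nesting judged from fixed-term sets with identical random
structure); non-nested pairs are marked not applicable. A singular variance
estimate (a random-effect variance at the boundary) is reported in the
result diagnostics, never silently dropped. Residuals and fitted values are
exported one-per-row so normality can be checked externally (Q–Q), rather
than building plots into the pipeline.

## Synthetic-data generator

The generator is phenomenological: it produces data with the statistical
structure the analysis assumes, and makes no claim of biomechanical
fidelity.

**Eyeblink trials.** Per group, CR incidence follows a logistic learning
curve over days 1–10 (`asymptote / (1 + exp(−slope(day − half_day)))`) and
a plateau probability over days 11–20. The CR waveform is an alpha-function
kernel `A·u·exp(1−u)`, `u = (t−onset)/(peak−onset)`: smooth, unimodal,
zero before onset, peaking exactly at the drawn peak latency, with a fast
rise (≈ 4 % of rise time to cross 10 % of amplitude) so detected onsets
track injected onsets to within ~10 ms at typical amplitudes. Peak
latencies are normal around the ISI with a group-specific spread — the
timing-precision manipulation — truncated *symmetrically* about the ISI
(to [ISI−c, ISI+c], c = min(ISI−120, 960−ISI)) so truncation never moves
the configured mean. Onsets are truncated normals in [55, min(495,
peak−40)]; amplitudes grow linearly over days within a phase and are
clipped to [0.12, 0.95]. The UR is a half-cosine rise (15 ms) with
exponential decay (80 ms), amplitude ~N(5.0, 0.25) raw units, present on
US-bearing trials at CS onset + ISI; paired trials superimpose CR and UR.
White Gaussian sensor noise (sd 0.08 raw ≈ 0.016 normalized) and a
per-trial baseline offset are added everywhere. Artifacts — signed 80 ms
half-sine transients, 2 % of trials by default — are injected strictly
inside the pre-CS window, so the validity filter is their only detector.
Noise level, artifact rate and amplitude are generator choices, not
measured quantities.

Default group effects follow the study's qualitative results: standard
mice acquire faster (asymptote 0.93, half-day 3.0 vs 0.83, 4.5), enriched
mice time more tightly (peak sd 55 vs 90 ms at ISI 250; 110 vs 180 ms at
ISI 500) and produce slightly smaller amplitudes. Magnitudes are
configuration, not constants.

**Motor assays** are drawn at the design cardinalities with per-group
means, trial-level noise and per-mouse random intercepts (the variance the
mouse random effect exists to absorb). Rotarod latencies are clipped at
the 300 s ceiling. Ladder runs are emitted as actual rung-touch sequences
whose front-paw placements land high with probability p/100, so the scored
landing-rule percent has expectation p; hind-paw touches are inserted and
never scored. Default group effects: enriched mice start higher on rotarod
and ladder; beam and grip differences are small relative to mouse-level
spread, so the group tests for them are usually non-significant — matching
the study's pattern.

**Determinism.** All randomness flows from one seed through per-session
`SeedSequence` children, so identical configs give byte-identical datasets,
sessions can be generated independently in any order, and the full study
streams one session (~240 traces) at a time.

**What passing tests do and do not show.** The generator has no per-mouse
heterogeneity in eyeblink acquisition (the learning curve is a group
property), no slow drifts or state changes (arousal, walking bouts), no
short-latency startle responses, and artifacts only in the pre-CS window.
Parameter-recovery results therefore certify the pipeline's correctness on
data satisfying its assumptions, not robustness to every failure mode of
real recordings. Conversely, detection is noise-limited near the flat top
of the CR kernel: single-trial peak latencies carry ~25 ms argmax jitter
at the default noise level (symmetric, so means are unbiased) — this is a
property of argmax detection on smooth responses, and real data behave the
same way.

## Problem sizes and calibration checks

The acceptance computation simulates the full study design (12 vs 16 mice,
20 days × 240 trials, all four motor assays) — about 134,400 traces — and
runs in a few minutes streaming. Type-I calibration of the mixed-model
group test uses 200 null simulations of a grip-sized design (27 mice × 8
observations, mouse-level plus trial-level noise, no group effect) and
requires the empirical rejection rate at α = 0.05 to land in [0.02, 0.09],
the two-sided binomial band around 0.05 for 200 draws. Timing-precision
monotonicity is checked on a 3-point sd grid (40/80/160 ms) with ~1,080
CS-only trials per grid point.

## Known limitations

* The amplitude-covariate model and amplitude-matched re-analysis assume
  the enriched group's amplitude IQR is a meaningful benchmark; with few
  enriched CRs it is noisy, and a zero-width IQR collapses the subset.
* The containment df rule is exact for balanced random-intercept designs
  and conservative for strongly unbalanced ones.
* The crossed random-effects fits (rotarod's trial, ladder's run) use a
  single-group variance-component formulation, which is exact but slow for
  the ladder's 5,670 rows (~10 s).
* `MixedLM` occasionally reports a boundary (singular) variance estimate
  on small or homogeneous simulated datasets; results carry a diagnostic
  message and the fixed-effect tests then approach their OLS counterparts.
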