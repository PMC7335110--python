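# Methods

This note documents the models, numerical choices and design decisions
behind `shuttlecsd`, and what the synthetic cohorts do and do not establish
about real recordings.

## Signal model and transforms

A laminar recording is a channels × samples field potential Φ with channel 0
most superficial, uniform contact spacing Δz (default 50 µm) and a
trial-relative time origin (recordings carry a 200-ms pre-trial baseline,
`t0 = −0.2 s`).  The processing order is fixed: bad-channel interpolation →
artifact handling → spatial smoothing → CSD.

- **Bad channels** are replaced sample-wise by linear interpolation between
  the nearest good channels above and below; a bad channel at either edge
  copies its nearest good neighbour.
- **Artifacts.** Samples at/after the aversive-stimulus onset are cropped
  (shock clipping), and a trial is flagged rejected when any channel exceeds
  `amplitude_sd_threshold` robust standard deviations (1.4826 × median
  absolute deviation per channel).  The default threshold of 10 targets
  gross movement artifacts; clean synthetic trials clear it by a wide
  margin (their maxima sit near 5–6 robust SDs).  The original workflow
  marked artifacts manually, so the automatic rule is a stated stand-in
  and manual rejection lists can be supplied instead.
- **Smoothing** convolves each time sample across channels with a
  normalized 9-point Hamming window (span 8 × 50 µm = 400 µm),
  edge-replicated so depth-constant profiles pass unchanged.
- **CSD** is the negated second spatial difference with differential grid
  n (default 1).  Boundary channels are computed under edge replication and
  flagged in a validity mask (policy `replicate`), or set NaN (policy
  `drop`).  The AVREC includes the flagged channels by default so that the
  channel count in its denominator equals the full array; excluding them is
  one keyword away.  Spacing enters in millimetres, so with potentials in
  mV the CSD is in mV/mm².
- **Layer assignment** finds contiguous channel clusters (≥ 2 channels)
  whose −CSD crosses 5 pre-stimulus SDs inside the onset window
  (0–80 ms); among clusters whose earliest crossing lies within 5 ms of the
  global earliest, the shallower becomes III/IV and the deeper Vb, with
  I/II, Va and VI filling the remaining ranges.  Anything ambiguous raises
  rather than guessing; a manual map (or the generator's ground-truth map)
  is accepted verbatim after validation.  The thresholds were set so that
  noise-level fluctuations cannot seed a cluster; they are not sensitive
  choices for template-like evoked profiles.

## Feature extraction

Features are RMS values over half-open windows `[t0, t0 + 0.5 s)` selected
by sample-start time: CS-onset windows for tone indices 1–4, a late
500–1000 ms variant, a whole-trace window running from trial start to the
compartment crossing (or window end), and choice-locked windows anchored at
the tone preceding the response — last CS onset strictly before the
crossing for hits/false alarms, the 4th CS for misses, and the last CS
whose window fits the trial for correct rejections, with back-indexed
anchors (response−1..−3) for the time-resolved analysis.  For correct
rejections in jittered 12–15 s trials the anchor rule "last fitting CS" is
our resolution of an ambiguity; nothing downstream depends on ±1 tone.
Signals are the AVREC plus the signed mean CSD of each laminar band.
z-scoring is within subject × session × window × signal with the n−1
standard deviation; degenerate groups yield missing values and a warning,
never infinities.

## Behavioral statistics

d′ uses standard-normal quantiles of the hit rate and the relative
intertrial-shuttle rate (fraction of intertrial intervals containing a
shuttle — the normalization is a package decision, configurable by
pre-aggregating differently).  Rates are clipped to `[1/(2N), 1 − 1/(2N)]`
so d′ stays finite at perfect scores; the learning criterion is strictly
d′ > 1 on three consecutive sessions.

## Mixed-effects logistic model

`MixedLogit` fits `logit P(y=1) = β₀ + β₁ x + z'u_i` with a subject random
intercept or correlated intercept + slope.  Estimation maximizes the
Laplace-approximated marginal likelihood: per-group penalized Newton modes
(tolerance 1e-10, concave objective), an unconstrained outer
parameterization (log-SDs, atanh correlation), BFGS with pooled-GLM
starting values, gradient tolerance 1e-8, 200 iterations.  Runs whose BFGS
line search stalls at a numerically zero gradient count as converged.
Singular or non-converged slope models fall back to the intercept-only
model with a warning, mirroring common practice.  Standard errors come from
the numerically differentiated Hessian of the marginal log-likelihood; β
p-values are two-sided Wald z-tests.  Complete separation in the pooled
start triggers a warning flag.  On a shared dataset the fits agree with
`lme4::glmer` (Laplace) to ~3 decimals in coefficients, standard errors,
variance components and log-likelihood; those reference numbers are frozen
into the test suite.

Effect sizes use the latent-scale variance decomposition with distribution
variance π²/3: σ²f is the variance of the fitted fixed-effect predictor
over the data; σ²r is the random-intercept variance, or for slope models
the per-observation `z'Σz` averaged over the design (one of several
conventions; chosen for being exact under the fitted model).  R²m bands:
small ≤ 0.1 < medium < 0.25 ≤ large.  Ties in the per-layer R²max are
broken superficial-to-deep.

## Repeated-measures ANOVA

`rm_anova` first aggregates trials to subject × cell means, so denominator
degrees of freedom are subject-level, then computes balanced
sums of squares for one or two within factors.  Generalized eta squared is
`SS_effect / (SS_effect + SS_subjects + Σ error SS)`.  No sphericity
correction is applied by default (an explicit design choice; the
uncorrected dfs are what the summary reports).  A degenerate design with
zero effect and zero error sums of squares reports F = 0, p = 1.  Holm
correction and paired t-tests delegate to statsmodels/scipy behind the
package surface.

## Synthetic cohort generator

The generator produces the study conditions every downstream stage is
validated against: multiple subjects × sessions × trials of laminar LFP
plus behavior, with serialized ground truth.

**Templates.** Each layer contributes a Hann-profiled current sink in its
band with flanking return sources (3 channels each side), charge-balanced
exactly per time column, sharing an alpha-like difference-of-exponentials
time course (τ_rise 10 ms, τ_decay 60 ms, ≈ 250 ms duration) shifted by
feedforward latencies: III/IV 12 ms and Vb 14 ms first, then I/II 22 ms,
Va 26 ms, VI 30 ms.  Base sink strengths favour the granular band
(1.0 vs 0.5–0.8).  The LFP is the exact discrete inverse of the CSD
operator (double cumulative summation, integration constants zero), so the
round-trip identity holds to machine precision on interior channels.

**Trial structure.** 200-ms tones at 1.5-s ISI (1.7-s onset spacing); Go
windows 6 s (4 tones), NoGo windows uniform 12–15 s with tones filling the
window; responses, when they occur, are uniform between the second tone and
the window end; tone presentation stops at the crossing.

**Decision and amplitude model.** One latent evidence draw e ~ N(0,1) per
trial sets the response log-odds `bias(contingency) + u_s + (β + w_s)·e`
with subject random intercept u_s ~ N(0, 0.5²) and slope w_s ~ N(0, 0.2²),
biases +1.2 (Go/detection) and −1.2 (NoGo) giving ≈ 77% hit and ≈ 25%
false-alarm rates.  The same e modulates every layer's template amplitude:
`1 + c·[Go] + a(1 + g(k−1))·e + q_s + jitter` at tone k, with evidence
coupling a = 0.3, accumulation gain g = 0.2, subject amplitude offset
q_s ~ N(0, 0.1²) and trial-level gain jitter ~ N(0, 0.3²).  A per-layer
weight map scales the modulated part, so effects can be confined to, e.g.,
supragranular channels.  Noise has two parts: white sensor noise
(SD 0.005) and spatially smooth ongoing activity (SD 0.01, Gaussian
correlation over ~3 channels) that the CSD largely cancels — mirroring why
CSD is preferred over referential LFP in the first place.

**The incorrect-choice null.** Because responding couples to e in both
contingencies, false alarms sit in the high-evidence tail and misses in the
low tail; the contingency offset c is set, by Gauss–Hermite quadrature over
(e, u_s, w_s) and the classes' expected anchor tone indices, to the value
that equalizes the two classes' expected amplitudes at their choice-locked
windows.  "No accuracy signal between FA and miss" is therefore a
structural property of the default configuration, not a fitted outcome;
the quadrature is verified against Monte-Carlo in the tests.

**Calibration.** β = 0.55, a = 0.3, g = 0.2, jitter 0.3 and the noise SDs
were chosen together—before the acceptance checks were wired—so that the
default cohort reproduces the qualitative effect-size regime of a trained
discrimination animal: a medium-band contingency effect (R²m ≈ 0.15–0.2),
detection-phase frequency R²m ≈ 0, significant choice effects that grow
toward the response, and the FA/miss null.  Dedicated study conditions
raise β/g (accumulation cohort) or confine the layer weights (supragranular
cohort).

**Reproducibility.** Every trial draws from a fresh generator seeded by
(seed, subject, phase, session, trial), so single trials regenerate in
isolation and cohorts are byte-identical across runs; HDF5 output disables
modification-time tracking to keep file checksums stable.

## What the synthetic cohorts do not show

The generator emulates the statistical structure assumed by the analyses —
latency-ordered sink/source templates, logistic choice with subject
heterogeneity, evidence accumulation across tone repeats — not the
biophysics of extracellular fields, electrode drift, oscillatory ongoing
activity, behavioral learning dynamics across sessions (a flat performance
level is simulated), or realistic artifact morphology.  Passing recovery
tests therefore establishes the correctness of the transforms and
estimators under the assumed model, not the validity of that model for any
particular dataset.

## Problem sizes

The test and acceptance cohorts use 8 subjects × 1–2 sessions × 60 trials
per phase (≈ 1,000–2,000 trials), the scale of the experimental design the
package targets; estimator studies use 50 recovery and 100 permutation
replicates at 8 × 500 observations.  These sizes make every property
checkable in minutes on one CPU while keeping class counts (≈ 100+ per
minority outcome) large enough for stable mixed-model fits.
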