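# Methods notes

## The belief model

The dynamic belief model treats the stop-signal rate r as a latent state
that persists between trials with probability α and is otherwise redrawn
from a generic beta prior π with mean *pm* and concentration *scale*
(shape parameters a = pm·scale, b = (1−pm)·scale — the standard
mean/concentration parameterization; the alternative reading of *scale* as
a single shape parameter was considered and rejected because it leaves the
prior mean unparameterized). Between trials the predictive distribution is
the α-mixture of the previous posterior and π; observing the trial category
applies a Bernoulli likelihood (r for stop, 1−r for go). p(Stop) is the
predictive mean, computed before the trial's category is seen, so the
series is strictly causal: permuting future trials cannot change past
estimates, which the tests assert directly.

Two limits anchor the implementation. At α = 1 nothing is forgotten and
p(Stop) must equal the conjugate beta-Bernoulli posterior predictive
(pm·scale + #stops)/(scale + #trials); the discretized filter matches this
closed form to < 5·10⁻⁵. At α = 0 every trial is forgotten and p(Stop) is
constant at pm. For intermediate α the model is well approximated by a
causal exponential linear filter; a 1-D search over the filter's decay
gives r > 0.99 agreement at α = 0.8 on 400-trial sequences.

**Discretization.** Beliefs live on the midpoints of 100 equal-width bins
of (0, 1), renormalized each step. Midpoints avoid the beta density's
endpoint singularities; both the mixture and the Bayes update are closed on
this representation, and all arithmetic stays in linear space (masses never
approach underflow at session lengths of a few hundred trials). Doubling
the grid changes no p(Stop) value by more than 0.002.

**Default parameters** α = 0.8, pm = 0.25, scale = 4: pm matches the
design's stop fraction, scale keeps the generic prior weakly informative
(equivalent to four pseudo-trials), and α = 0.8 sits in the range typical
of sequential-effect modeling of binary event streams. The defaults are
exposed in configuration; `fit_params` supports per-subject grid-search
selection by maximizing the p(Stop)–RT correlation, with a first-in-grid
tie-break and a p-value flag for null data.

## Task simulation

Trials are i.i.d. Bernoulli(0.25) stop assignments; foreperiods uniform on
1–5 s; each trial occupies foreperiod + 1 s response window + 2 s ITI.
Sessions are fixed-length scans (300 volumes × TR 2 s = 600 s), so trials
that would not complete before the session end are dropped — a session
holds approximately 100 trials, and a 78-subject cohort averages ~395
trials per subject.

Subjects follow the race model: the go process finishes at

    go_mu + slowing·(p(Stop) − 0.25) + drift·index/100 + N(0, rt_noise²)

floored at 80 ms (a Gaussian finishing time is sufficient for every
property tested here; an ex-Gaussian is a documented extension point). On
stop trials a response is emitted iff the finishing time beats SSD + SSRT.
The SSD staircase starts at 200 ms, moves ±67 ms after each stop trial
(up after success), clamps to [0, 900] ms, and carries across the four
sessions of a subject (restarting it per session would re-pay the start-up
transient four times). Go errors occur at rate `go_fail_prob`, split evenly
between premature presses and omissions; finishing times beyond the 1 s
window are additional omissions. Neither premature presses nor omissions
carry an RT, so the go response rate is 1 − go_fail_prob up to the small
late-omission contribution.

Two mechanisms push the long-run stop-success rate above the staircase's
50% fixed point: the climb from the 200 ms start to the tracking point
(~410 ms) is traversed mostly through successful stops, and the positive
within-session drift keeps the tracking point moving away from the
staircase. With the defaults these contribute about +1.5 and +0.3
percentage points, landing near the 52% observed in practice.

## Behavioral estimators

Critical SSD is the mean SSD over stop trials after discarding the initial
transient — all stop trials before the first staircase reversal, and at
least five. A reversal-based burn-in was chosen over a last-N average or a
psychometric fit because it is robust, respects the staircase's tracking
interpretation, and recovers the generating SSRT on simulation (bias
≈ +2 ms, SD ≈ 15 ms at 100 stop trials). SSRT is the median go-success RT
minus the critical SSD — an identity the summary preserves exactly, so any
bias in one estimator maps one-for-one (opposite sign) into the other.
Medians of even counts average the central pair. The sequential effect uses
go-success trials only (the trials that carry an RT), Pearson r with the
t-transform p-value at n − 2 df.

## First-level GLM

The canonical HRF is the conventional double-gamma (peak 6 s, undershoot
16 s, unit dispersions, 1:6 ratio) sampled at TR/16 over 32 s and scaled to
unit peak; its temporal derivative is a finite difference. Each session
contributes: an onset regressor (unit impulses at every trial's fixation
onset), its derivative, the available parametric modulators in the fixed
order (p(Stop) of GS, SSD of SS, p(Stop) of SS, SSD of SE, p(Stop) of SE;
empty strata are omitted with a logged warning), and a constant. Modulators
are mean-centered per session before convolution — so a constant modulator
contributes nothing and contrasts are invariant to modulator shifts — and
are *not* serially orthogonalized by default, keeping each estimate
order-independent; the legacy sequential orthogonalization is available
behind `orthogonalize_modulators=True` for comparison, since with the
modeled order the two conventions genuinely differ. The temporal-derivative
column does not enter the reported contrasts.

Regressors are built on the oversampled grid of the full session and only
then truncated to the retained volumes, so responses to early trials bleed
correctly into the data that survives discarding the first five volumes.
Low frequencies are removed with a per-session discrete-cosine basis
(cutoff 1/128 Hz) projected out of both data and design at fit time.
Serial correlation uses a two-pass fit: OLS, lag-1 residual autocorrelation
pooled within sessions (never across boundaries), AR(1) whitening with the
first sample of each session scaled by √(1−ρ²), refit. ρ may also be fixed
by the caller; ρ = 0 reproduces OLS exactly. Degrees of freedom discount
both the design and the filtering basis. The ±1 contrasts on the GS
p(Stop) modulator average that column's betas across sessions and are
exact negations of each other.

The OLS-residual estimate of ρ is biased low by roughly k/n (k regressors
including the cosine basis, n volumes); at the default design size this is
≈ 0.05. The calibration tests therefore check ρ recovery on long series
with compact designs, where the bias is negligible.

## Group statistics

The second-level regression uses NS, HA, RD, age, and *two* gender
indicator columns with no separate intercept — the indicators span it, so
adding a constant to the dependent variable moves only the gender
coefficients (the single-indicator-plus-intercept coding gives identical
trait coefficients). The two-slope comparison is the classical
pooled-residual-variance t with n₁ + n₂ − 4 df. Trait inter-correlation
screening supports the Bonferroni α = 0.05/3 convention. Summary-statistic
entry points for the t-test allow checking printed group means/SDs without
raw data; standard scipy/statsmodels routines do the underlying inference.

## The synthetic cohort

Trait subscores are truncated (by rejection), rounded normals on their
subscale ranges — NS 4.1 ± 2.5 on 0–13 (truncation at 0 reproduces the
positive skew of NS qualitatively), HA per gender (women 7.44 ± 4.40, men
5.07 ± 4.12) on 0–22, RD 6.4 ± 2.4 on 0–9 — drawn independently, so
pairwise correlations are pure sampling noise (SD 1/√77 at n = 78).
Item-level questionnaire structure is not modeled. Behavioral parameters:
base finishing time 620 ms with a between-subject SD of 90 ms, true SSRT ~
N(204, 42²) ms, slowing ~ N(500, 150) ms per unit p(Stop), within-subject
RT noise 100 ms, go failure 0.022, drift 6 ms per 100 trials. The slowing
default follows from the closed form r ≈ s·σ_p/√(s²σ_p² + σ_noise²): the
generating belief model's p(Stop) has σ_p ≈ 0.072 at the default
parameters, so s = 500 and σ_noise = 100 give a mean sequential effect of
≈ 0.33. The `calibrate` operation re-derives such values by coordinate
search (direct mapping for go failure and SSRT mean; bracketed 1-D root
finding with common random numbers for drift and slowing) and reports the
best achieved values when a target is unreachable.

ROI BOLD is generated *from the first-level design operator itself*:
signal = onset columns × 1.0 + GS p(Stop) columns × subject amplitude,
plus stationary AR(1) noise (ρ = 0.3, SD 0.3). Amplitudes follow the
trait-linkage model amp = base + slope·trait + N(0, 0.8) with negative NS
slopes for pre-SMA (−0.09), MFG/lOFC (−0.12) and IPL (−0.105) and a
negative HA slope for the thalamus (−0.052); amplitude units are arbitrary
(contrast values are unitless), and the slopes are set so trait-explained
variance lands in the 6–12% range. Model-consistency by construction makes
GLM recovery exact in expectation; `hrf_peak_jitter_s` injects per-subject
HRF mismatch for robustness studies. A ground-truth record of every
generating parameter accompanies each bundle, and the whole bundle is a
deterministic function of (config, master seed) via a spawned seed
hierarchy — no global random state anywhere.

**What the generator does not emulate:** motion and physiological noise,
spatial structure (everything is ROI-level; no smoothing, normalization or
voxelwise inference), item-level trait structure, RT distribution shape
beyond its first two moments, and any trait–behavior coupling (trait
scores influence only the ROI amplitudes, mirroring the null behavioral
findings in this design). Passing tests therefore validate the estimators
and the pipeline's statistical machinery, not the physiological realism of
the input data.

## Problem sizes

The test suite simulates cohorts of 8–78 subjects at 10–400 trials each and
fits GLMs on 1 180-volume four-session series; null calibrations use
300–400 replications, which bounds false-positive-rate estimates to about
±2 percentage points. The acceptance script runs the full 78-subject,
four-session default study and completes in a few seconds on one CPU.
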