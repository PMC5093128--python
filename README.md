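# stopbayes

Simulation and analysis of proactive control in the stop-signal task (SST):
trial-by-trial Bayesian estimation of stop-signal probability, race-model
SSRT estimation, first-level GLM with parametric modulators on ROI BOLD, and
cohort-level trait regressions — all driven by a synthetic cohort generator,
so the full chain is testable without any human data.

## The problem

In the SST, participants respond quickly to a go signal but must withhold
the response when a stop signal follows after a variable stop-signal delay
(SSD). People anticipate: when recent history suggests a stop signal is
likely, they slow down. `stopbayes` quantifies this anticipation with a
dynamic belief model, a Bayesian observer that assumes the latent stop rate
r_k persists between trials with probability α and is otherwise redrawn from
a beta prior with mean *pm* and concentration *scale*:

    p(r_k | s_1..k-1) = α · p(r_{k-1} | s_1..k-1) + (1 − α) · π(r_k)

followed by a Bernoulli Bayes update once trial k's category s_k (go = 0,
stop = 1) is observed. The probability of an impending stop signal,
p(Stop), is the mean of the predictive distribution — computed strictly
before the trial, so it is a genuine prior belief. The **sequential
effect** is the per-subject Pearson correlation between p(Stop) and go-trial
RT: anticipatory slowing.

Around this model the package provides:

- **Task simulation** (`stopbayes.sst`): schedules with a 75/25 go/stop mix,
  a 1-up/1-down SSD staircase (start 200 ms, step 67 ms), and race-model
  subjects — a response is emitted iff the go process finishes before
  SSD + SSRT.
- **Behavioral statistics** (`stopbayes.behavior`): critical SSD (the delay
  at which stopping succeeds half the time, estimated as the post-transient
  staircase mean), SSRT = median go RT − critical SSD, and the sequential
  effect with its t-transform p-value.
- **First-level GLM** (`stopbayes.glm`): canonical double-gamma HRF +
  temporal derivative on trial onsets, five ordered parametric modulators
  (p(Stop) of GS trials, SSD and p(Stop) of SS trials, SSD and p(Stop) of SE
  trials), 1/128 Hz discrete-cosine high-pass, AR(1) prewhitening, and ±1
  contrasts on the GS p(Stop) modulator.
- **Group statistics** (`stopbayes.stats`): pooled-variance t-tests with
  Cohen's d (also from printed summary statistics), Pearson/Spearman
  correlations, the second-level regression of contrast values on NS, HA,
  RD, age and two gender indicators (no separate intercept), and the
  classical two-slope comparison test.
- **Synthetic cohort** (`stopbayes.cohort`): 78 subjects (48 women) with
  Tridimensional Personality Questionnaire scores (novelty seeking, harm
  avoidance, reward dependence) drawn from truncated rounded normals,
  race-model behavior calibrated to the reference cohort, and ROI BOLD whose
  p(Stop)-modulation amplitude loads negatively on NS (pre-SMA, MFG/lOFC,
  IPL) or HA (thalamus).
- **Pipeline** (`stopbayes.pipeline` / `stopbayes` CLI): the whole chain as
  a pure function of (config, seed).

## Worked example

```python
from stopbayes import run_all, RunConfig

result = run_all(RunConfig(), seed=7)
print(result.report_text)
```

prints (abridged):

```
Task performance:
  go response rate 97.5 +- 1.5 %
  stop success rate 51.9 +- 1.2 %
  median GoRT 630 +- 95 ms
  SSRT 200 +- 34 ms
  sequential effect r 0.33 +- 0.10; significant in 76/78 subjects

Second-level trait regressions (GS_pstop>0 contrast):
  mfg_lofc: NS coef -0.1365 (t = -3.21, p = 0.0020); simple r = -0.325 (p = 0.0037, R^2 = 10.5 %)
  thalamus: HA coef -0.0761 (t = -2.69, p = 0.0090); simple r = -0.300 (p = 0.0076, R^2 = 9.0 %)
```

Reading this: the staircase tracked stopping at ~52% success; subjects
slowed by about 500 ms per unit of p(Stop), yielding a mean sequential
effect of r = 0.33 that is individually significant in nearly every
subject; the race-model estimator recovers the generating SSRT
distribution (mean 204 ms); and the second-level regression recovers the
negative NS and HA loadings placed on the ROI amplitudes, at effect sizes
(R² ≈ 6–12%) in the range reported for real cohorts.

The same stages are available from the shell:

```sh
stopbayes run --seed 7 --out-dir results/
stopbayes make-cohort --seed 1 --out-dir cohort/
stopbayes pstop --events cohort/events/sub01_events.tsv --out with_pstop.tsv
stopbayes behavior --events with_pstop.tsv --out summary.tsv
```

## Layout

```
src/stopbayes/
  dbm.py       dynamic belief model and p(Stop) estimation
  sst.py       schedules, staircase, race-model simulation
  behavior.py  SSRT, critical SSD, sequential effect
  glm.py       HRF, design matrix, AR(1) GLM, contrasts
  stats.py     t-tests, correlations, second-level regression, slopes
  cohort.py    synthetic study generator and calibration
  pipeline.py  end-to-end orchestration
  cli.py       command-line interface
docs/methods.md  model and design notes
```
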