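"""Synthetic study generator: traits, task behavior, and trait-linked ROI BOLD.

Emulates a cohort of 78 adults (48 women) performing four 100-trial
stop-signal sessions, with Tridimensional Personality Questionnaire scores
matching the study population: NS 4.1 +- 2.5 (range 0-13), HA 6.5 +- 4.4
(range 0-22) with women scoring higher than men (7.44 +- 4.40 vs
5.07 +- 4.12), RD 6.4 +- 2.4 (range 0-9).  Trait draws are truncated,
rounded normals and the three subscales are generated independently.

Each subject's task behavior comes from the race-model simulator with
subject-level parameters drawn around the cohort defaults: go finishing
time 620 ms (between-subject SD 90 ms), true SSRT ~ Normal(204, 42^2),
anticipatory slowing ~ Normal(500, 150) ms per unit p(Stop), residual RT
noise 100 ms, go failure probability 0.022, and a within-session slowing
drift of 6 ms per 100 trials (the tracking lag this induces, together with
the staircase's climb from its 200 ms start, pushes the stop-success rate
slightly above one half, as observed).

ROI BOLD series for four regions (anterior pre-SMA, MFG/lOFC, right IPL,
thalamus) are synthesized directly from the first-level design operator:
each subject's GS p(Stop)-modulation amplitude is a linear function of a
trait (negative NS loading for the three cortical ROIs, negative HA loading
for the thalamus) plus subject-level scatter, and AR(1) observation noise
is added.  Model-consistency by construction makes GLM recovery exact in
expectation; an HRF-jitter option provides a model-mismatch variant.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy import optimize

from .dbm import DBMParams
from .sst import SubjectProfile, make_schedule, simulate_subject, write_events_tsv
from .glm import HRFSpec, build_design, modulator_contrast_weights

__all__ = ["TraitSpec", "ROISpec", "CohortConfig", "CohortBundle", "generate_cohort", "calibrate", "write_bundle"]


@dataclass(frozen=True)
class TraitSpec:
    """Truncated-rounded-normal marginal for one questionnaire subscale."""

    mean: float
    sd: float
    low: int
    high: int
    mean_female: float | None = None
    sd_female: float | None = None
    mean_male: float | None = None
    sd_male: float | None = None


@dataclass(frozen=True)
class ROISpec:
    """Linear trait-to-amplitude model for one region of interest."""

    trait: str  # "ns" | "ha" | "rd"
    base: float
    slope: float
    noise_sd: float


@dataclass(frozen=True)
class CohortConfig:
    """Generating parameters for a full synthetic study."""

    n_subjects: int = 78
    n_female: int = 48
    trials_per_session: int = 100
    n_sessions: int = 4
    stop_fraction: float = 0.25

    ns: TraitSpec = TraitSpec(4.1, 2.5, 0, 13)
    ha: TraitSpec = TraitSpec(6.5, 4.4, 0, 22, mean_female=7.44, sd_female=4.40, mean_male=5.07, sd_male=4.12)
    rd: TraitSpec = TraitSpec(6.4, 2.4, 0, 9)
    age_mean: float = 30.2
    age_sd: float = 10.2
    age_range: tuple[float, float] = (18.0, 65.0)

    go_mu_ms: float = 620.0
    go_mu_sd_ms: float = 90.0  # between-subject spread of the base finishing time
    ssrt_mean_ms: float = 204.0
    ssrt_sd_ms: float = 42.0
    slowing_mean_ms: float = 500.0
    slowing_sd_ms: float = 150.0
    rt_noise_sd_ms: float = 100.0
    go_fail_prob: float = 0.022
    drift_ms_per_100trials: float = 6.0

    dbm: DBMParams = DBMParams()  # generating-side belief model

    rois: dict = field(
        default_factory=lambda: {
            "pre_sma": ROISpec("ns", 1.0, -0.09, 0.8),
            "mfg_lofc": ROISpec("ns", 1.0, -0.12, 0.8),
            "ipl": ROISpec("ns", 1.0, -0.105, 0.8),
            "thalamus": ROISpec("ha", 1.0, -0.052, 0.8),
        }
    )
    onset_amplitude: float = 1.0
    bold_noise_sd: float = 0.3
    bold_ar1_rho: float = 0.3
    hrf_peak_jitter_s: float = 0.0  # >0 injects per-subject HRF model mismatch
    n_volumes_per_session: int = 300
    tr_s: float = 2.0

    def __post_init__(self) -> None:
        if self.n_female > self.n_subjects:
            raise ValueError("n_female cannot exceed n_subjects")
        for trait in (self.ns, self.ha, self.rd):
            if trait.sd < 0:
                raise ValueError("trait SD must be nonnegative")
            if not trait.low <= trait.mean <= trait.high:
                raise ValueError(f"trait mean {trait.mean} outside [{trait.low}, {trait.high}]")


@dataclass
class CohortBundle:
    """Everything one synthetic study produces, plus its ground truth."""

    config: CohortConfig
    seed: int
    cohort: pd.DataFrame  # one row per subject: id, gender, age, traits
    profiles: dict  # subject_id -> SubjectProfile
    events: dict  # subject_id -> event-log DataFrame (with generating pstop)
    bold: dict  # subject_id -> DataFrame (session column + one column per ROI)
    ground_truth: dict  # generating parameters, JSON-serializable


def _draw_trait(rng: np.random.Generator, mean: float, sd: float, low: int, high: int, n: int) -> np.ndarray:
    """Rounded draw from a normal truncated to the subscale range."""
    a, b = (low - mean) / sd, (high - mean) / sd
    vals = sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)
    return np.clip(np.round(vals), low, high).astype(int)


def _ar1_noise(rng: np.random.Generator, n: int, rho: float, sd: float) -> np.ndarray:
    e = rng.normal(0.0, sd, size=n)
    out = np.empty(n)
    out[0] = e[0] / np.sqrt(1.0 - rho**2)  # stationary start
    for t in range(1, n):
        out[t] = rho * out[t - 1] + e[t]
    return out


def generate_cohort(
    config: CohortConfig | None = None,
    seed: int = 0,
    include_bold: bool = True,
) -> CohortBundle:
    """Generate a complete synthetic study, deterministically from ``seed``.

    Per subject: trait draws, a subject profile drawn around the cohort
    defaults, a simulated 4 x 100-trial event log with the generating
    belief model's p(Stop) attached, and (optionally) ROI BOLD series whose
    GS p(Stop)-modulation amplitude follows the trait-linkage model.
    """
    if config is None:
        config = CohortConfig()
    root = np.random.SeedSequence(seed)
    cohort_ss, *subject_ss = root.spawn(config.n_subjects + 1)
    rng = np.random.default_rng(cohort_ss)
    n = config.n_subjects

    genders = np.array(["F"] * config.n_female + ["M"] * (n - config.n_female))
    ages = sps.truncnorm.rvs(
        (config.age_range[0] - config.age_mean) / config.age_sd,
        (config.age_range[1] - config.age_mean) / config.age_sd,
        loc=config.age_mean,
        scale=config.age_sd,
        size=n,
        random_state=rng,
    )
    ns = _draw_trait(rng, config.ns.mean, config.ns.sd, config.ns.low, config.ns.high, n)
    # HA differs by gender; draw each group from its own marginal
    ha = np.empty(n, dtype=int)
    fem = genders == "F"
    ha[fem] = _draw_trait(rng, config.ha.mean_female, config.ha.sd_female, config.ha.low, config.ha.high, int(fem.sum()))
    ha[~fem] = _draw_trait(rng, config.ha.mean_male, config.ha.sd_male, config.ha.low, config.ha.high, int((~fem).sum()))
    rd = _draw_trait(rng, config.rd.mean, config.rd.sd, config.rd.low, config.rd.high, n)

    go_mu = rng.normal(config.go_mu_ms, config.go_mu_sd_ms, size=n)
    ssrt_true = rng.normal(config.ssrt_mean_ms, config.ssrt_sd_ms, size=n)
    slowing = rng.normal(config.slowing_mean_ms, config.slowing_sd_ms, size=n)
    amp_noise = {roi: rng.normal(0.0, spec.noise_sd, size=n) for roi, spec in config.rois.items()}

    profiles, events, bold = {}, {}, {}
    truth_subjects = {}
    n_trials = config.trials_per_session * config.n_sessions
    for i in range(n):
        sid = f"sub{i + 1:02d}"
        srng = np.random.default_rng(subject_ss[i])
        profile = SubjectProfile(
            subject_id=sid,
            gender=str(genders[i]),
            age=float(np.round(ages[i], 1)),
            ns=int(ns[i]),
            ha=int(ha[i]),
            rd=int(rd[i]),
            go_mu_ms=float(max(go_mu[i], 300.0)),
            go_sigma_ms=config.go_mu_sd_ms,
            ssrt_true_ms=float(max(ssrt_true[i], 60.0)),
            slowing_coef_ms=float(slowing[i]),
            rt_noise_sd_ms=config.rt_noise_sd_ms,
            go_fail_prob=config.go_fail_prob,
            drift_ms_per_100trials=config.drift_ms_per_100trials,
        )
        schedule = make_schedule(
            n_trials,
            stop_fraction=config.stop_fraction,
            seed=srng,
            n_sessions=config.n_sessions,
            session_duration_s=config.n_volumes_per_session * config.tr_s,
        )
        ev = simulate_subject(
            profile, schedule, dbm_params=config.dbm, seed=srng, stop_fraction=config.stop_fraction
        )
        profiles[sid] = profile
        events[sid] = ev

        trait_vals = {"ns": ns[i], "ha": ha[i], "rd": rd[i]}
        amps = {
            roi: spec.base + spec.slope * float(trait_vals[spec.trait]) + float(amp_noise[roi][i])
            for roi, spec in config.rois.items()
        }
        truth_subjects[sid] = {
            "go_mu_ms": profile.go_mu_ms,
            "ssrt_true_ms": profile.ssrt_true_ms,
            "slowing_coef_ms": profile.slowing_coef_ms,
            "roi_amplitudes": amps,
        }

        if include_bold:
            hrf = HRFSpec(tr_s=config.tr_s)
            if config.hrf_peak_jitter_s > 0.0:
                hrf = dataclasses.replace(
                    hrf, peak_delay_s=hrf.peak_delay_s + srng.normal(0.0, config.hrf_peak_jitter_s)
                )
            X = build_design(ev, hrf, config.n_volumes_per_session)
            beta = np.zeros(len(X.column_names))
            for j, name in enumerate(X.column_names):
                if name.endswith("_onset"):
                    beta[j] = config.onset_amplitude
                elif name.endswith("_GS_pstop"):
                    beta[j] = 0.0  # filled per ROI below
            signal_base = X.values @ beta
            w_gs = modulator_contrast_weights(X, "GS_pstop")
            gs_cols = X.values[:, w_gs != 0].sum(axis=1)
            roi_df = {"session": np.repeat(
                np.arange(1, config.n_sessions + 1), np.array(X.n_volumes)
            )}
            for roi in config.rois:
                noise = _ar1_noise(srng, X.values.shape[0], config.bold_ar1_rho, config.bold_noise_sd)
                roi_df[roi] = signal_base + amps[roi] * gs_cols + noise
            bold[sid] = pd.DataFrame(roi_df)

    cohort = pd.DataFrame(
        {
            "subject_id": [f"sub{i + 1:02d}" for i in range(n)],
            "gender": genders,
            "age": np.round(ages, 1),
            "ns": ns,
            "ha": ha,
            "rd": rd,
        }
    )
    ground_truth = {
        "seed": seed,
        "config": _config_to_dict(config),
        "subjects": truth_subjects,
    }
    return CohortBundle(
        config=config,
        seed=seed,
        cohort=cohort,
        profiles=profiles,
        events=events,
        bold=bold,
        ground_truth=ground_truth,
    )


def _config_to_dict(config: CohortConfig) -> dict:
    def enc(v):
        if dataclasses.is_dataclass(v) and not isinstance(v, type):
            return {f.name: enc(getattr(v, f.name)) for f in dataclasses.fields(v)}
        if isinstance(v, dict):
            return {k: enc(x) for k, x in v.items()}
        if isinstance(v, (np.floating, np.integer)):
            return v.item()
        if isinstance(v, tuple):
            return list(v)
        return v

    return enc(config)


def write_bundle(bundle: CohortBundle, out_dir) -> None:
    """Write cohort TSV, per-subject event logs and BOLD TSVs, and ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.cohort.to_csv(out / "cohort.tsv", sep="\t", index=False)
    ev_dir = out / "events"
    ev_dir.mkdir(exist_ok=True)
    for sid, ev in bundle.events.items():
        write_events_tsv(ev, ev_dir / f"{sid}_events.tsv")
    if bundle.bold:
        bold_dir = out / "bold"
        bold_dir.mkdir(exist_ok=True)
        for sid, df in bundle.bold.items():
            df.to_csv(bold_dir / f"{sid}_bold.tsv", sep="\t", index=False, float_format="%.6f")
    with open(out / "ground_truth.json", "w") as fh:
        json.dump(bundle.ground_truth, fh, indent=2)


class CalibrationError(RuntimeError):
    """Raised when the coordinate search cannot reach the requested targets."""


#: target name -> (free parameter, direct | search, bracket for the search)
_CALIBRATION_MAP = {
    "go_response_rate": ("go_fail_prob", "direct", None),
    "ssrt": ("ssrt_mean_ms", "direct", None),
    "ss_rate": ("drift_ms_per_100trials", "search", (-80.0, 80.0)),
    "sequential_effect": ("slowing_mean_ms", "search", (0.0, 1500.0)),
}


def _cohort_means(config: CohortConfig, seed: int, n_subjects: int) -> dict:
    from .behavior import summarize  # local import avoids a cycle

    cfg = dataclasses.replace(config, n_subjects=n_subjects, n_female=min(config.n_female, n_subjects))
    bundle = generate_cohort(cfg, seed=seed, include_bold=False)
    rows = [summarize(ev) for ev in bundle.events.values()]
    return {
        "go_response_rate": float(np.mean([r.go_response_rate for r in rows])),
        "ss_rate": float(np.mean([r.ss_rate for r in rows])),
        "ssrt": float(np.mean([r.ssrt_ms for r in rows])),
        "sequential_effect": float(np.mean([r.seq_effect_r for r in rows])),
    }


def calibrate(
    config: CohortConfig,
    targets: dict[str, float],
    tolerance: float | dict[str, float] = 0.02,
    seed: int = 0,
    n_subjects_eval: int = 24,
) -> CohortConfig:
    """Coordinate search tuning designated free parameters to cohort targets.

    Supported targets: mean ``go_response_rate`` (frees ``go_fail_prob``,
    direct mapping), mean ``ssrt`` (shifts ``ssrt_mean_ms``), mean
    ``ss_rate`` (frees the within-session drift), mean ``sequential_effect``
    (frees the mean slowing coefficient).  Simulated evaluations reuse the
    same seed (common random numbers), which makes each 1-D objective smooth
    in its parameter.  Tolerances are relative unless given per target.
    """
    unknown = set(targets) - set(_CALIBRATION_MAP)
    if unknown:
        raise ValueError(f"unsupported calibration targets: {sorted(unknown)}")
    cfg = config
    for name, target in targets.items():
        param, kind, bracket = _CALIBRATION_MAP[name]
        if kind == "direct":
            if name == "go_response_rate":
                cfg = dataclasses.replace(cfg, go_fail_prob=float(np.clip(1.0 - target, 0.0, 0.2)))
            else:  # ssrt: shift the generating mean by the measured bias
                measured = _cohort_means(cfg, seed, n_subjects_eval)[name]
                cfg = dataclasses.replace(cfg, ssrt_mean_ms=cfg.ssrt_mean_ms + (target - measured))
        else:

            def objective(value: float, _p=param, _n=name) -> float:
                trial_cfg = dataclasses.replace(cfg, **{_p: float(value)})
                return _cohort_means(trial_cfg, seed, n_subjects_eval)[_n] - target

            lo, hi = bracket
            f_lo, f_hi = objective(lo), objective(hi)
            if f_lo * f_hi > 0:
                raise CalibrationError(
                    f"target {name}={target} not bracketed in {bracket}: "
                    f"achieved [{f_lo + target:.4f}, {f_hi + target:.4f}]"
                )
            value = optimize.brentq(objective, lo, hi, xtol=1e-3 * (hi - lo))
            cfg = dataclasses.replace(cfg, **{param: float(value)})

    achieved = _cohort_means(cfg, seed, max(n_subjects_eval, 24))
    tol = tolerance if isinstance(tolerance, dict) else {k: tolerance for k in targets}
    failed = {
        k: (achieved[k], targets[k])
        for k in targets
        if abs(achieved[k] - targets[k]) > tol[k] * max(abs(targets[k]), 1e-12)
    }
    if failed:
        raise CalibrationError(f"calibration missed targets (achieved, wanted): {failed}")
    return cfg
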