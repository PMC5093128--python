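"""Stop-signal task schedules, staircase SSD tracking, and race-model subjects.

The task is a simple-RT stop-signal paradigm: each trial begins with a
fixation dot, the go signal appears after a uniform 1-5 s foreperiod, and on
a quarter of trials a stop signal follows the go signal after the stop
signal delay (SSD).  The SSD starts at 200 ms and moves by 67 ms — up after
a successful stop, down after a failed one — so that stopping succeeds about
half the time.  Simulated subjects obey the race model: a response is
emitted iff the go process finishes before SSD + SSRT.  Go finishing times
slow with the subject's trial-by-trial stop-signal expectancy p(Stop)
(the sequential effect) and drift linearly within the session.

Trial outcomes follow the standard four-way classification: go success (GS),
go error (GE, omission or premature press), stop success (SS), stop error
(SE).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .dbm import DBMParams, _discretized_beta

__all__ = [
    "StaircaseState",
    "SubjectProfile",
    "make_schedule",
    "staircase_step",
    "simulate_subject",
    "EVENT_COLUMNS",
]

RESPONSE_WINDOW_MS = 1000.0
ITI_S = 2.0
FOREPERIOD_RANGE_S = (1.0, 5.0)
SSD_START_MS = 200.0
SSD_STEP_MS = 67.0
SSD_MIN_MS = 0.0
SSD_MAX_MS = 900.0
RT_FLOOR_MS = 80.0

#: Event-log column order (TSV interface; missing values written as "NA").
EVENT_COLUMNS = [
    "subject_id",
    "session",
    "index",
    "trial_type",
    "onset_s",
    "foreperiod_s",
    "ssd_ms",
    "rt_ms",
    "outcome",
    "pstop",
]


@dataclass(frozen=True)
class StaircaseState:
    """One-up/one-down SSD tracker (step 67 ms, clamped to [0, 900] ms)."""

    ssd_ms: float = SSD_START_MS
    step_ms: float = SSD_STEP_MS
    min_ms: float = SSD_MIN_MS
    max_ms: float = SSD_MAX_MS

    def __post_init__(self) -> None:
        if self.step_ms <= 0:
            raise ValueError(f"step_ms must be positive, got {self.step_ms}")
        if not self.min_ms <= self.ssd_ms <= self.max_ms:
            raise ValueError(
                f"ssd_ms {self.ssd_ms} outside [{self.min_ms}, {self.max_ms}]"
            )


@dataclass(frozen=True)
class SubjectProfile:
    """Generative parameters and trait scores for one simulated subject.

    ``go_mu_ms``/``go_sigma_ms`` parameterize the Gaussian go finishing-time
    distribution (floored at 80 ms); ``ssrt_true_ms`` is the latency of the
    stop process in the race; ``slowing_coef_ms`` scales the RT increase per
    unit of p(Stop) above the nominal stop fraction; ``drift_ms_per_100trials``
    is a linear within-session slowing.  NS, HA and RD are Tridimensional
    Personality Questionnaire subscores (ranges 0-13, 0-22, 0-9).
    """

    subject_id: str
    gender: str  # "M" or "F"
    age: float
    ns: int
    ha: int
    rd: int
    go_mu_ms: float = 620.0
    go_sigma_ms: float = 90.0
    ssrt_true_ms: float = 204.0
    slowing_coef_ms: float = 500.0
    rt_noise_sd_ms: float = 100.0
    go_fail_prob: float = 0.022
    drift_ms_per_100trials: float = 6.0

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F"):
            raise ValueError(f"gender must be 'M' or 'F', got {self.gender!r}")
        for name, hi in (("ns", 13), ("ha", 22), ("rd", 9)):
            v = getattr(self, name)
            if not 0 <= v <= hi:
                raise ValueError(f"{name} must be in [0, {hi}], got {v}")
        for name in ("go_mu_ms", "go_sigma_ms", "ssrt_true_ms", "rt_noise_sd_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.go_fail_prob <= 0.2:
            raise ValueError(f"go_fail_prob must be in [0, 0.2], got {self.go_fail_prob}")


def make_schedule(
    n_trials: int,
    stop_fraction: float = 0.25,
    iti_s: float = ITI_S,
    foreperiod_range_s: tuple[float, float] = FOREPERIOD_RANGE_S,
    seed: int | np.random.Generator = 0,
    n_sessions: int = 1,
    session_duration_s: float | None = None,
) -> pd.DataFrame:
    """Randomized go/stop trial schedule with onsets.

    Trial types are i.i.d. Bernoulli(``stop_fraction``); foreperiods are
    uniform on ``foreperiod_range_s``.  Each trial occupies foreperiod +
    1 s response window + ITI, and onsets accumulate within a session;
    sessions restart the clock at zero.  If ``session_duration_s`` is set,
    trials that would not complete before the session ends are dropped (a
    session then holds *approximately* ``n_trials / n_sessions`` trials,
    as in a fixed-length scan).  Deterministic given ``seed``.

    Returns a DataFrame with columns session, index, trial_type ("go" /
    "stop"), onset_s, foreperiod_s.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0.0 <= stop_fraction < 1.0:
        raise ValueError("stop_fraction must be in [0, 1)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    is_stop = rng.random(n_trials) < stop_fraction
    fp = rng.uniform(*foreperiod_range_s, size=n_trials)
    dur = fp + RESPONSE_WINDOW_MS / 1000.0 + iti_s
    per_session = int(np.ceil(n_trials / n_sessions))
    session = np.arange(n_trials) // per_session + 1
    onset = np.empty(n_trials)
    for s in np.unique(session):
        m = session == s
        onset[m] = np.concatenate([[0.0], np.cumsum(dur[m])[:-1]])
    sched = pd.DataFrame(
        {
            "session": session,
            "index": np.arange(1, n_trials + 1),
            "trial_type": np.where(is_stop, "stop", "go"),
            "onset_s": onset,
            "foreperiod_s": fp,
        }
    )
    if session_duration_s is not None:
        fits = sched["onset_s"] + sched["foreperiod_s"] + RESPONSE_WINDOW_MS / 1000.0
        sched = sched[fits <= session_duration_s].reset_index(drop=True)
        sched["index"] = np.arange(1, len(sched) + 1)
    return sched


def staircase_step(state: StaircaseState, stop_outcome: str) -> StaircaseState:
    """Advance the tracker: +step after SS, -step after SE, then clamp."""
    if stop_outcome == "SS":
        ssd = state.ssd_ms + state.step_ms
    elif stop_outcome == "SE":
        ssd = state.ssd_ms - state.step_ms
    else:
        raise ValueError(f"stop_outcome must be 'SS' or 'SE', got {stop_outcome!r}")
    return replace(state, ssd_ms=float(np.clip(ssd, state.min_ms, state.max_ms)))


def simulate_subject(
    profile: SubjectProfile,
    schedule: pd.DataFrame,
    dbm_params: DBMParams | None = None,
    seed: int | np.random.Generator = 0,
    stop_fraction: float = 0.25,
) -> pd.DataFrame:
    """Simulate one subject's event log over a trial schedule.

    Per trial, the subject's generating belief model yields p(Stop) causally
    from the history; the go finishing time is

        go_mu + slowing_coef * (p(Stop) - stop_fraction)
              + drift * index / 100 + Gaussian noise,

    floored at 80 ms.  Go trials fail (GE) with ``go_fail_prob`` — half
    premature presses during the foreperiod, half omissions — or when the
    finishing time exceeds the 1 s response window.  Stop trials follow the
    race: a response is emitted iff finishing time < SSD + SSRT (outcome SE,
    with the finishing time as RT), otherwise SS.  The staircase updates
    after every stop trial and carries across sessions.  Deterministic given
    ``seed``.
    """
    if dbm_params is None:
        dbm_params = DBMParams()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    required = {"session", "index", "trial_type", "onset_s", "foreperiod_s"}
    if not required.issubset(schedule.columns):
        raise ValueError(f"schedule missing columns {required - set(schedule.columns)}")

    n = len(schedule)
    grid, pi = _discretized_beta(dbm_params.beta_a, dbm_params.beta_b, dbm_params.grid_size)
    pred = pi.copy()

    noise = rng.normal(0.0, profile.rt_noise_sd_ms, size=n)
    u_fail = rng.random(n)
    u_premature = rng.random(n)

    staircase = StaircaseState()
    rows: list[dict] = []
    types = schedule["trial_type"].to_numpy()
    for i in range(n):
        is_stop = types[i] == "stop"
        p = float(grid @ pred)
        finish = (
            profile.go_mu_ms
            + profile.slowing_coef_ms * (p - stop_fraction)
            + profile.drift_ms_per_100trials * (i + 1) / 100.0
            + noise[i]
        )
        finish = max(finish, RT_FLOOR_MS)

        ssd_ms: float | None = None
        rt_ms: float | None = None
        if not is_stop:
            if u_fail[i] < profile.go_fail_prob:
                outcome = "GE"  # premature press or omission, split evenly
                if u_premature[i] < 0.5:
                    rt_ms = None  # omission
                else:
                    rt_ms = None  # premature: press before go signal, no valid RT
            elif finish > RESPONSE_WINDOW_MS:
                outcome = "GE"  # omission: response window elapsed
            else:
                outcome = "GS"
                rt_ms = finish
        else:
            ssd_ms = staircase.ssd_ms
            if finish < ssd_ms + profile.ssrt_true_ms and finish <= RESPONSE_WINDOW_MS:
                outcome = "SE"
                rt_ms = finish
            else:
                outcome = "SS"
            staircase = staircase_step(staircase, outcome)

        rows.append(
            {
                "subject_id": profile.subject_id,
                "session": int(schedule["session"].iat[i]),
                "index": int(schedule["index"].iat[i]),
                "trial_type": types[i],
                "onset_s": float(schedule["onset_s"].iat[i]),
                "foreperiod_s": float(schedule["foreperiod_s"].iat[i]),
                "ssd_ms": ssd_ms,
                "rt_ms": rt_ms,
                "outcome": outcome,
                "pstop": p,
            }
        )

        # belief update with the true category
        post = pred * (grid if is_stop else 1.0 - grid)
        post /= post.sum()
        pred = dbm_params.alpha * post + (1.0 - dbm_params.alpha) * pi

    return pd.DataFrame(rows, columns=EVENT_COLUMNS)


def write_events_tsv(events: pd.DataFrame, path) -> None:
    """Write an event log as TSV with 'NA' for missing values, pstop to 6 dp."""
    out = events.copy()
    out["pstop"] = out["pstop"].map(lambda v: f"{v:.6f}")
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_events_tsv(path) -> pd.DataFrame:
    """Read an event-log TSV written by :func:`write_events_tsv`."""
    return pd.read_csv(path, sep="\t", na_values=["NA"])
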