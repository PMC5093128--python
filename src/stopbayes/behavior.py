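"""Per-subject behavioral statistics for the stop-signal task.

Provides the race-model SSRT estimate (median go RT minus the critical SSD,
the delay at which stopping succeeds half the time), response-rate
summaries, and the sequential effect — the Pearson correlation between the
trial-by-trial stop-signal expectancy p(Stop) and go RT, the behavioral
signature of proactive slowing.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BehavioralSummary",
    "critical_ssd",
    "ssrt",
    "sequential_effect",
    "summarize",
    "summarize_cohort",
]

MIN_STOP_TRIALS = 20
MIN_GS_TRIALS = 20
MIN_SEQ_TRIALS = 10
MIN_BURN_IN = 5  # stop trials always discarded before the critical-SSD mean


@dataclass(frozen=True)
class BehavioralSummary:
    """One subject's task summary.

    ``ssrt_ms`` equals ``median_gort_ms - critical_ssd_ms`` by construction.
    """

    subject_id: str
    n_go: int
    n_stop: int
    go_response_rate: float
    ss_rate: float
    median_gort_ms: float
    critical_ssd_ms: float
    ssrt_ms: float
    seq_effect_r: float
    seq_effect_p: float


def critical_ssd(events: pd.DataFrame) -> float:
    """Mean SSD over stop trials after the initial staircase transient.

    The staircase starts well below its tracking point, so early stop trials
    are discarded: everything before the first staircase reversal, and at
    least the first five stop trials.  The mean of the remaining SSDs
    estimates the delay at which stopping succeeds on half the stop trials.
    """
    ssd = events.loc[events["trial_type"] == "stop", "ssd_ms"].to_numpy(dtype=float)
    if ssd.size < MIN_STOP_TRIALS:
        raise ValueError(f"need >= {MIN_STOP_TRIALS} stop trials, got {ssd.size}")
    steps = np.sign(np.diff(ssd))
    # first reversal: first index where the step direction changes
    burn_in = MIN_BURN_IN
    nonzero = np.flatnonzero(steps != 0)
    if nonzero.size:
        first_dir = steps[nonzero[0]]
        rev = np.flatnonzero((steps != 0) & (steps != first_dir))
        if rev.size:
            burn_in = max(MIN_BURN_IN, int(rev[0]) + 1)
    burn_in = min(burn_in, ssd.size - MIN_BURN_IN)  # keep a usable tail
    return float(np.mean(ssd[burn_in:]))


def ssrt(events: pd.DataFrame) -> float:
    """Race-model SSRT: median go-success RT minus the critical SSD."""
    gs_rt = events.loc[events["outcome"] == "GS", "rt_ms"].to_numpy(dtype=float)
    if gs_rt.size < MIN_GS_TRIALS:
        raise ValueError(f"need >= {MIN_GS_TRIALS} GS trials, got {gs_rt.size}")
    return float(np.median(gs_rt) - critical_ssd(events))


def sequential_effect(events: pd.DataFrame) -> tuple[float, float]:
    """Pearson correlation between p(Stop) and go RT, with two-sided p.

    Restricted to go-success trials (a response and a valid RT exist).  The
    p-value comes from the t transform with n - 2 degrees of freedom.
    """
    gs = events[events["outcome"] == "GS"]
    p = gs["pstop"].to_numpy(dtype=float)
    rt = gs["rt_ms"].to_numpy(dtype=float)
    if p.size < MIN_SEQ_TRIALS:
        raise ValueError(f"need >= {MIN_SEQ_TRIALS} GS trials, got {p.size}")
    if np.std(p) == 0.0 or np.std(rt) == 0.0:
        raise ValueError("undefined correlation: zero variance in p(Stop) or RT")
    r, pval = stats.pearsonr(p, rt)
    return float(r), float(pval)


def summarize(events: pd.DataFrame) -> BehavioralSummary:
    """All behavioral summary statistics for one subject's event log."""
    subject_id = str(events["subject_id"].iat[0]) if "subject_id" in events else ""
    go = events[events["trial_type"] == "go"]
    stop = events[events["trial_type"] == "stop"]
    n_go, n_stop = len(go), len(stop)
    # responses on go trials: any valid RT (GS, or a premature/late press is
    # recorded without RT, hence counted as non-response)
    go_resp = int(go["rt_ms"].notna().sum())
    gs_rt = events.loc[events["outcome"] == "GS", "rt_ms"].to_numpy(dtype=float)
    c_ssd = critical_ssd(events)
    med = float(np.median(gs_rt))
    r, pval = sequential_effect(events)
    return BehavioralSummary(
        subject_id=subject_id,
        n_go=n_go,
        n_stop=n_stop,
        go_response_rate=go_resp / n_go,
        ss_rate=float((stop["outcome"] == "SS").mean()),
        median_gort_ms=med,
        critical_ssd_ms=c_ssd,
        ssrt_ms=med - c_ssd,
        seq_effect_r=r,
        seq_effect_p=pval,
    )


def summarize_cohort(event_logs: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """One-row-per-subject summary table over a cohort of event logs."""
    return pd.DataFrame([asdict(summarize(ev)) for ev in event_logs.values()])
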