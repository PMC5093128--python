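"""Dynamic belief model: trial-by-trial Bayesian estimation of p(Stop).

The model assumes the latent stop-trial rate ``r_k`` persists from one trial
to the next with probability ``alpha`` and is redrawn from a generic beta
prior (mean ``pm``, concentration ``scale``) with probability ``1 - alpha``.
Observing the trial category (go = 0, stop = 1) updates the belief by Bayes'
rule with a Bernoulli likelihood.  The prior probability that the upcoming
trial carries a stop signal — p(Stop) — is the mean of the predictive
distribution over ``r_k``, computed *before* the trial's category is seen.

The belief distribution is discretized on a fixed grid over (0, 1): the beta
density is evaluated at the midpoints of ``grid_size`` equal-width bins and
renormalized.  Both the mixture step and the Bayes update are closed on this
representation, and midpoints avoid the density singularities at 0 and 1 when
``scale`` puts mass near the endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "DBMParams",
    "BeliefState",
    "make_prior",
    "update_posterior",
    "advance_prior",
    "pstop",
    "run_sequence",
    "exponential_filter",
    "best_filter_decay",
    "fit_params",
]

#: Default analysis-side parameters: pm matches the task's stop fraction,
#: alpha sits in the range typical for sequential-effect modeling of binary
#: event streams, and scale = 4 keeps the generic prior weakly informative.
DEFAULT_ALPHA = 0.8
DEFAULT_PM = 0.25
DEFAULT_SCALE = 4.0
DEFAULT_GRID_SIZE = 100

_NORM_TOL = 1e-10


@dataclass(frozen=True)
class DBMParams:
    """Parameters of the dynamic belief model.

    Parameters
    ----------
    alpha : float
        Belief-persistence probability in [0, 1].  ``alpha = 0`` forgets
        everything each trial; ``alpha = 1`` accumulates evidence forever
        (the conjugate beta-Bernoulli limit).
    pm : float
        Mean of the generic beta prior over the stop rate, in (0, 1).
    scale : float
        Concentration of the beta prior (``a + b``); larger values make the
        prior tighter around ``pm``.
    grid_size : int
        Number of discretization points for the stop rate, >= 10.
    """

    alpha: float = DEFAULT_ALPHA
    pm: float = DEFAULT_PM
    scale: float = DEFAULT_SCALE
    grid_size: int = DEFAULT_GRID_SIZE

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if not 0.0 < self.pm < 1.0:
            raise ValueError(f"pm must be in (0, 1), got {self.pm}")
        if not self.scale > 0.0:
            raise ValueError(f"scale must be positive, got {self.scale}")
        if int(self.grid_size) != self.grid_size or self.grid_size < 10:
            raise ValueError(f"grid_size must be an integer >= 10, got {self.grid_size}")

    @property
    def beta_a(self) -> float:
        return self.pm * self.scale

    @property
    def beta_b(self) -> float:
        return (1.0 - self.pm) * self.scale


@dataclass
class BeliefState:
    """Discretized belief over the stop rate at one point in the sequence.

    ``predictive_mass`` is p(r_k | s_1..k-1), the prior for trial ``k``
    before its category is observed; ``posterior_mass`` is p(r_k | s_1..k)
    after the Bayes update.  ``prior_mass`` caches the discretized generic
    prior pi(r) used by the mixture step.
    """

    r_grid: np.ndarray
    predictive_mass: np.ndarray
    posterior_mass: np.ndarray
    prior_mass: np.ndarray = field(repr=False)
    trial_index: int = 1

    def __post_init__(self) -> None:
        n = len(self.r_grid)
        for name in ("predictive_mass", "posterior_mass", "prior_mass"):
            vec = getattr(self, name)
            if len(vec) != n:
                raise ValueError(f"{name} length {len(vec)} != grid length {n}")
        for name in ("predictive_mass", "posterior_mass"):
            total = float(np.sum(getattr(self, name)))
            if abs(total - 1.0) > 1e-8:
                raise ValueError(f"{name} sums to {total}, expected 1")


def _discretized_beta(a: float, b: float, grid_size: int) -> tuple[np.ndarray, np.ndarray]:
    """Beta(a, b) density at bin midpoints of (0, 1), renormalized to a pmf."""
    grid = (np.arange(grid_size) + 0.5) / grid_size
    dens = stats.beta.pdf(grid, a, b)
    return grid, dens / dens.sum()


def make_prior(params: DBMParams) -> BeliefState:
    """Initial belief state: predictive and posterior both equal pi(r).

    p(Stop) for the very first trial is therefore the prior mean ``pm`` up
    to discretization error.
    """
    grid, pi = _discretized_beta(params.beta_a, params.beta_b, params.grid_size)
    return BeliefState(
        r_grid=grid,
        predictive_mass=pi.copy(),
        posterior_mass=pi.copy(),
        prior_mass=pi,
        trial_index=1,
    )


def update_posterior(state: BeliefState, outcome: int) -> BeliefState:
    """Bayes update of the predictive mass by the observed trial category.

    Likelihood is ``r`` for a stop trial (outcome 1) and ``1 - r`` for a go
    trial (outcome 0).
    """
    if outcome not in (0, 1):
        raise ValueError(f"outcome must be 0 (go) or 1 (stop), got {outcome!r}")
    lik = state.r_grid if outcome == 1 else 1.0 - state.r_grid
    unnorm = lik * state.predictive_mass
    total = unnorm.sum()
    if total <= 0.0 or not np.isfinite(total):
        raise FloatingPointError("posterior mass vanished; belief state degenerate")
    return replace(state, posterior_mass=unnorm / total)


def advance_prior(state: BeliefState, params: DBMParams) -> BeliefState:
    """Mixture step to the next trial's predictive distribution.

    p(r_k | s_1..k-1) = alpha * p(r_{k-1} | s_1..k-1) + (1 - alpha) * pi(r).
    Normalization is preserved by construction.
    """
    pred = params.alpha * state.posterior_mass + (1.0 - params.alpha) * state.prior_mass
    return replace(state, predictive_mass=pred, trial_index=state.trial_index + 1)


def pstop(state: BeliefState) -> float:
    """Mean of the predictive distribution: the probability of a stop signal."""
    return float(np.dot(state.r_grid, state.predictive_mass))


def run_sequence(categories, params: DBMParams | None = None) -> np.ndarray:
    """p(Stop) for every trial of a go/stop sequence, strictly causally.

    ``values[k]`` is computed from trials ``0..k-1`` only; ``values[0]`` is
    the prior mean ``pm`` (up to discretization).

    Parameters
    ----------
    categories : sequence of {0, 1}
        Trial categories, go = 0 and stop = 1, in presentation order.
    params : DBMParams, optional
        Model parameters; defaults to ``DBMParams()``.

    Returns
    -------
    numpy.ndarray
        One probability per trial.
    """
    if params is None:
        params = DBMParams()
    cats = np.asarray(categories)
    if cats.size == 0:
        raise ValueError("categories must be non-empty")
    if not np.isin(cats, (0, 1)).all():
        raise ValueError("categories must contain only 0 (go) and 1 (stop)")

    # Vectorized loop over trials; grid ops only.
    grid, pi = _discretized_beta(params.beta_a, params.beta_b, params.grid_size)
    lik_stop, lik_go = grid, 1.0 - grid
    pred = pi.copy()
    out = np.empty(cats.size)
    for k, s in enumerate(cats):
        out[k] = grid @ pred
        post = pred * (lik_stop if s == 1 else lik_go)
        post /= post.sum()
        pred = params.alpha * post + (1.0 - params.alpha) * pi
    return out


def exponential_filter(categories, decay: float, init: float) -> np.ndarray:
    """Causal exponentially-weighted running estimate of the stop rate.

    ``values[k]`` is the normalized exponentially weighted average of the
    categories before trial ``k``, seeded with a unit pseudo-observation at
    ``init``.  In the ``decay -> 1`` limit it approaches the cumulative stop
    fraction.  Serves as the linear-filter comparison for the belief model,
    which it approximates closely for moderate-to-high ``alpha``.
    """
    if not 0.0 < decay < 1.0:
        raise ValueError(f"decay must be in (0, 1), got {decay}")
    if not 0.0 <= init <= 1.0:
        raise ValueError(f"init must be a probability, got {init}")
    cats = np.asarray(categories, dtype=float)
    out = np.empty(cats.size)
    num, den = init, 1.0  # weighted sum and total weight, pseudo-count seed
    for k, s in enumerate(cats):
        out[k] = num / den
        num = decay * num + s
        den = decay * den + 1.0
    return out


def best_filter_decay(
    categories, pstop_series, grid: np.ndarray | None = None, init: float = DEFAULT_PM
) -> tuple[float, float]:
    """1-D search for the filter decay best matching a p(Stop) series.

    Returns ``(decay, pearson_r)`` maximizing the correlation between the
    exponential-filter estimate and ``pstop_series``.
    """
    if grid is None:
        grid = np.linspace(0.05, 0.99, 95)
    best = (float(grid[0]), -np.inf)
    for d in grid:
        f = exponential_filter(categories, float(d), init)
        r = np.corrcoef(f, pstop_series)[0, 1]
        if r > best[1]:
            best = (float(d), float(r))
    return best


def fit_params(categories, go_rt, search_grid) -> tuple[DBMParams, float, float]:
    """Choose DBM parameters maximizing the sequential-effect correlation.

    Evaluates each candidate parameter set on the Pearson correlation
    between its p(Stop) series (restricted to go trials carrying an RT) and
    the go RTs; ties break to the first candidate in grid order.

    Parameters
    ----------
    categories : sequence of {0, 1}
        Full trial sequence.
    go_rt : array-like
        RTs aligned with the go trials that have a response, NaN elsewhere
        on go trials; length equal to the number of go trials OR the full
        sequence length with NaN on stop trials.
    search_grid : iterable of DBMParams
        Candidate parameter sets, in tie-break order.

    Returns
    -------
    (DBMParams, float, float)
        Best parameters, their correlation, and its two-sided p-value.
        A best correlation not significantly above zero is flagged by the
        returned p-value (no exception).
    """
    cats = np.asarray(categories)
    rt = np.asarray(go_rt, dtype=float)
    if rt.size == cats.size:
        rt = rt[cats == 0]
    valid = np.isfinite(rt)
    if valid.sum() < 20:
        raise ValueError("need at least 20 go trials with RT")
    if np.nanstd(rt[valid]) == 0.0:
        raise ValueError("go RT vector has zero variance")

    candidates = list(search_grid)
    if not candidates:
        raise ValueError("search_grid is empty")
    best: tuple[DBMParams, float, float] | None = None
    for params in candidates:
        ps = run_sequence(cats, params)[cats == 0][valid]
        if np.std(ps) == 0.0:
            r, p = 0.0, 1.0
        else:
            r, p = stats.pearsonr(ps, rt[valid])
        if best is None or r > best[1]:
            best = (params, float(r), float(p))
    return best
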