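"""First-level GLM on ROI BOLD time series with parametric modulators.

Trial onsets (the appearance of the fixation point) are convolved with the
canonical double-gamma hemodynamic response function and its temporal
derivative.  Five parametric modulators enter in a fixed order — p(Stop) of
GS trials, SSD of SS trials, p(Stop) of SS trials, SSD of SE trials,
p(Stop) of SE trials — each mean-centered per session before convolution.
Sessions are concatenated block-diagonally with per-session constants.  Low
frequencies below 1/128 Hz are removed with a discrete-cosine basis
projected out of both data and design at fit time, and serial correlation
is handled by a two-pass AR(1) prewhitening fit.  Contrasts (here the +-1
contrasts on the GS p(Stop) modulator) are reported with t statistics from
the whitened model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "HRFSpec",
    "DesignMatrix",
    "GLMFit",
    "canonical_hrf",
    "build_design",
    "dct_basis",
    "fit_glm_ar1",
    "contrast",
    "modulator_contrast_weights",
]

HIGHPASS_CUTOFF_HZ = 1.0 / 128.0
KERNEL_LENGTH_S = 32.0
DEFAULT_DISCARD_VOLUMES = 5

#: Modulator definitions in the modeled order: (label, outcome, column).
MODULATORS = [
    ("GS_pstop", "GS", "pstop"),
    ("SS_ssd", "SS", "ssd_ms"),
    ("SS_pstop", "SS", "pstop"),
    ("SE_ssd", "SE", "ssd_ms"),
    ("SE_pstop", "SE", "pstop"),
]


@dataclass(frozen=True)
class HRFSpec:
    """Canonical double-gamma HRF parameters (seconds) and sampling grid."""

    tr_s: float = 2.0
    oversampling: int = 16
    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_disp_s: float = 1.0
    undershoot_disp_s: float = 1.0
    p_u_ratio: float = 6.0
    include_derivative: bool = True

    def __post_init__(self) -> None:
        for name in ("tr_s", "peak_delay_s", "undershoot_delay_s", "peak_disp_s", "undershoot_disp_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.oversampling < 1:
            raise ValueError("oversampling must be >= 1")


@dataclass
class DesignMatrix:
    """Concatenated-session design with the filtering basis attached."""

    column_names: list[str]
    values: np.ndarray
    tr_s: float
    n_volumes: list[int]  # retained volumes per session
    session_boundaries: np.ndarray  # row offsets, length n_sessions + 1
    dct: np.ndarray = field(repr=False, default=None)  # high-pass basis, same rows

    def __post_init__(self) -> None:
        if self.values.shape[0] != sum(self.n_volumes):
            raise ValueError("design rows do not match retained volumes")
        if not np.isfinite(self.values).all():
            raise ValueError("design matrix contains non-finite entries")
        if self.dct is None:
            self.dct = np.empty((self.values.shape[0], 0))


@dataclass
class GLMFit:
    """Whitened-model estimates from the two-pass AR(1) fit."""

    column_names: list[str]
    betas: np.ndarray
    sigma2: float
    rho: float
    dof: float
    cov_betas: np.ndarray = field(repr=False, default=None)
    contrast_values: dict = field(default_factory=dict)


def canonical_hrf(spec: HRFSpec | None = None) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sampled canonical HRF kernel, its temporal derivative, and time grid.

    The kernel is the difference of two gamma densities (peak at ~6 s,
    undershoot at ~16 s, ratio 1:6) sampled every ``tr_s / oversampling``
    seconds over 32 s; the derivative is a finite difference of the sampled
    kernel.  The kernel is scaled to unit peak.
    """
    if spec is None:
        spec = HRFSpec()
    dt = spec.tr_s / spec.oversampling
    t = np.arange(0.0, KERNEL_LENGTH_S, dt)
    peak = stats.gamma.pdf(t, spec.peak_delay_s / spec.peak_disp_s, scale=spec.peak_disp_s)
    under = stats.gamma.pdf(
        t, spec.undershoot_delay_s / spec.undershoot_disp_s, scale=spec.undershoot_disp_s
    )
    h = peak - under / spec.p_u_ratio
    h = h / h.max()
    dh = np.gradient(h, dt)
    return h, dh, t


def dct_basis(n_volumes: int, tr_s: float, cutoff_hz: float = HIGHPASS_CUTOFF_HZ) -> np.ndarray:
    """Discrete-cosine high-pass basis (without the constant term).

    Includes the cosines with frequency below ``cutoff_hz``; the number of
    retained functions is floor(2 * n * TR * cutoff).
    """
    order = int(np.floor(2.0 * n_volumes * tr_s * cutoff_hz))
    t = np.arange(n_volumes)
    cols = [
        np.sqrt(2.0 / n_volumes) * np.cos(np.pi * (2 * t + 1) * k / (2.0 * n_volumes))
        for k in range(1, order + 1)
    ]
    return np.column_stack(cols) if cols else np.empty((n_volumes, 0))


def _session_regressors(
    ev: pd.DataFrame,
    spec: HRFSpec,
    n_volumes: int,
    discard_volumes: int,
    orthogonalize: bool = False,
) -> tuple[list[str], np.ndarray]:
    """Regressors for one session: onset, derivative, modulators, constant.

    Regressors are built on the oversampled grid of the *full* session (so
    early responses bleed correctly into retained volumes), convolved, then
    sampled at TR and truncated to the retained volumes.
    """
    h, dh, _ = canonical_hrf(spec)
    os = spec.oversampling
    dt = spec.tr_s / os
    n_hi = n_volumes * os
    session_dur = n_volumes * spec.tr_s

    onsets = ev["onset_s"].to_numpy(dtype=float)
    if (onsets < 0).any() or (onsets >= session_dur).any():
        raise ValueError("trial onset outside the session duration")
    idx = np.minimum((onsets / dt).round().astype(int), n_hi - 1)

    def conv(stick_vals: np.ndarray, positions: np.ndarray, kernel: np.ndarray) -> np.ndarray:
        stick = np.zeros(n_hi)
        np.add.at(stick, positions, stick_vals)
        x = np.convolve(stick, kernel)[:n_hi]
        return x[::os][discard_volumes:n_volumes]

    names = ["onset", "deriv"]
    cols = [conv(np.ones_like(idx, dtype=float), idx, h), conv(np.ones_like(idx, dtype=float), idx, dh)]

    for label, outcome, column in MODULATORS:
        stratum = ev[ev["outcome"] == outcome]
        vals = stratum[column].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(stratum) == 0 or vals.size == 0:
            logger.warning("modulator %s omitted: no %s trials in session", label, outcome)
            continue
        centered = stratum[column].to_numpy(dtype=float) - vals.mean()
        pos = idx[np.flatnonzero((ev["outcome"] == outcome).to_numpy())]
        col = conv(centered, pos, h)
        if orthogonalize and len(cols) > 2:
            # legacy serial orthogonalization against earlier modulators only
            P = np.column_stack(cols[2:])
            col = col - P @ np.linalg.lstsq(P, col, rcond=None)[0]
        names.append(label)
        cols.append(col)

    names.append("const")
    cols.append(np.ones(n_volumes - discard_volumes))
    return names, np.column_stack(cols)


def build_design(
    events: pd.DataFrame,
    spec: HRFSpec | None = None,
    n_volumes_per_session: int = 300,
    discard_volumes: int = DEFAULT_DISCARD_VOLUMES,
    orthogonalize_modulators: bool = False,
) -> DesignMatrix:
    """Multi-session design matrix from an event log.

    Each session contributes an onset regressor (unit impulses at fixation
    onsets, all trials), its temporal derivative, the available parametric
    modulators in the modeled order, and a constant, concatenated
    block-diagonally.  The first ``discard_volumes`` volumes of each session
    are dropped (signal equilibration), with event responses preserved.
    Modulators are *not* serially orthogonalized against one another by
    default, which keeps their estimates order-independent; pass
    ``orthogonalize_modulators=True`` for the legacy sequential behavior.
    """
    if spec is None:
        spec = HRFSpec()
    sessions = sorted(events["session"].unique())
    blocks, all_names, n_kept = [], [], []
    for s in sessions:
        ev = events[events["session"] == s].reset_index(drop=True)
        names, X = _session_regressors(
            ev, spec, n_volumes_per_session, discard_volumes, orthogonalize_modulators
        )
        blocks.append(X)
        all_names.append([f"s{s}_{n}" for n in names])
        n_kept.append(X.shape[0])

    total = sum(n_kept)
    ncols = sum(b.shape[1] for b in blocks)
    values = np.zeros((total, ncols))
    dct_blocks = []
    r = c = 0
    for X, nk in zip(blocks, n_kept):
        values[r : r + nk, c : c + X.shape[1]] = X
        dct_blocks.append(dct_basis(nk, spec.tr_s))
        r += nk
        c += X.shape[1]
    # block-diagonal DCT basis
    dct_cols = sum(b.shape[1] for b in dct_blocks)
    dct = np.zeros((total, dct_cols))
    r = c = 0
    for b in dct_blocks:
        dct[r : r + b.shape[0], c : c + b.shape[1]] = b
        r += b.shape[0]
        c += b.shape[1]

    boundaries = np.concatenate([[0], np.cumsum(n_kept)])
    return DesignMatrix(
        column_names=[n for ns in all_names for n in ns],
        values=values,
        tr_s=spec.tr_s,
        n_volumes=n_kept,
        session_boundaries=boundaries,
        dct=dct,
    )


def _project_out(dct: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Residualize columns of M against the (orthonormal-per-block) DCT basis."""
    if dct.shape[1] == 0:
        return M
    return M - dct @ (dct.T @ M)


def fit_glm_ar1(y: np.ndarray, X: DesignMatrix, rho: float | None = None) -> GLMFit:
    """Two-pass AR(1) prewhitened least-squares fit of one ROI time series.

    Pass 1 is OLS on the high-pass-filtered data and design; the AR(1)
    coefficient is the lag-1 autocorrelation of its residuals pooled over
    sessions.  Pass 2 whitens data and design by the AR(1) transform
    (first observation of each session scaled by sqrt(1 - rho^2)) and
    refits.  Degrees of freedom discount both the design and the filtering
    basis.  Passing ``rho`` explicitly skips the estimation pass; ``rho=0``
    reproduces the OLS fit exactly.
    """
    y = np.asarray(y, dtype=float)
    if y.shape[0] != X.values.shape[0]:
        raise ValueError(f"time series length {y.shape[0]} != design rows {X.values.shape[0]}")
    Xf = _project_out(X.dct, X.values)
    yf = _project_out(X.dct, y[:, None])[:, 0]

    rank = np.linalg.matrix_rank(Xf)
    if rank < Xf.shape[1]:
        # name a collinear column for the error message
        _, R = np.linalg.qr(Xf)
        bad = [X.column_names[i] for i in np.flatnonzero(np.abs(np.diag(R)) < 1e-8)]
        raise np.linalg.LinAlgError(f"design is rank deficient; collinear columns: {bad}")

    if rho is None:
        beta, *_ = np.linalg.lstsq(Xf, yf, rcond=None)
        resid = yf - Xf @ beta
        # pooled lag-1 autocorrelation, never crossing session boundaries
        num = den = 0.0
        for a, b in zip(X.session_boundaries[:-1], X.session_boundaries[1:]):
            r = resid[a:b]
            num += float(r[1:] @ r[:-1])
            den += float(r @ r)
        rho = 0.0 if den == 0.0 else num / den
    rho = float(np.clip(rho, -0.99, 0.99))  # keep the transform stationary

    def whiten(M: np.ndarray) -> np.ndarray:
        W = np.empty_like(M)
        for a, b in zip(X.session_boundaries[:-1], X.session_boundaries[1:]):
            W[a] = np.sqrt(1.0 - rho**2) * M[a]
            W[a + 1 : b] = M[a + 1 : b] - rho * M[a:b - 1]
        return W

    Xw = whiten(Xf)
    yw = whiten(yf[:, None])[:, 0]
    beta_w, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid_w = yw - Xw @ beta_w
    dof = y.shape[0] - Xf.shape[1] - X.dct.shape[1]
    if dof <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    sigma2 = float(resid_w @ resid_w / dof)
    cov = sigma2 * np.linalg.pinv(Xw.T @ Xw)
    return GLMFit(
        column_names=X.column_names,
        betas=beta_w,
        sigma2=sigma2,
        rho=rho,
        dof=float(dof),
        cov_betas=cov,
    )


def contrast(fit: GLMFit, weights) -> tuple[float, float]:
    """Contrast estimate and t statistic from the whitened model."""
    w = np.asarray(weights, dtype=float)
    if w.shape[0] != len(fit.column_names):
        raise ValueError("contrast weight length does not match design columns")
    est = float(w @ fit.betas)
    var = float(w @ fit.cov_betas @ w)
    t = 0.0 if var == 0.0 else est / np.sqrt(var)
    return est, t


def modulator_contrast_weights(fit_or_design, label: str, sign: float = 1.0) -> np.ndarray:
    """+-1 contrast on a modulator, averaged over the sessions carrying it."""
    names = fit_or_design.column_names
    hits = [i for i, n in enumerate(names) if n.endswith(f"_{label}")]
    if not hits:
        raise ValueError(f"no design column for modulator {label!r}")
    w = np.zeros(len(names))
    w[hits] = sign / len(hits)
    return w
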