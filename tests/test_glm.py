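"""First-level GLM: HRF, design construction, AR(1) fitting, contrasts."""

import numpy as np
import pandas as pd
import pytest

from stopbayes.glm import (
    DesignMatrix,
    HRFSpec,
    build_design,
    canonical_hrf,
    contrast,
    dct_basis,
    fit_glm_ar1,
    modulator_contrast_weights,
)


def _single_trial_events(onset=10.0, outcome="GS", pstop=0.3, ssd=None):
    return pd.DataFrame(
        [
            {
                "subject_id": "s",
                "session": 1,
                "index": 1,
                "trial_type": "go" if outcome in ("GS", "GE") else "stop",
                "onset_s": onset,
                "foreperiod_s": 2.0,
                "ssd_ms": ssd,
                "rt_ms": 600.0,
                "outcome": outcome,
                "pstop": pstop,
            }
        ]
    )


def _toy_design(n=2000, k=3, seed=0):
    rng = np.random.default_rng(seed)
    X = np.column_stack([rng.normal(size=(n, k)), np.ones(n)])
    return DesignMatrix(
        column_names=[f"x{i}" for i in range(k)] + ["const"],
        values=X,
        tr_s=2.0,
        n_volumes=[n],
        session_boundaries=np.array([0, n]),
        dct=None,
    )


class TestHRF:
    def test_peak_time_in_canonical_range(self):
        h, _, t = canonical_hrf()
        assert 4.0 <= t[np.argmax(h)] <= 7.0

    def test_single_undershoot_sign_change(self):
        h, _, t = canonical_hrf()
        after_peak = h[np.argmax(h):]
        signs = np.sign(after_peak[np.abs(after_peak) > 1e-6])
        changes = int((np.diff(signs) != 0).sum())
        assert changes == 1

    def test_derivative_integrates_to_zero(self):
        h, dh, t = canonical_hrf()
        dt = t[1] - t[0]
        assert abs(dh.sum() * dt) < 1e-3 * h.max()


class TestDesign:
    def test_single_impulse_equals_shifted_hrf(self):
        spec = HRFSpec()
        ev = _single_trial_events(onset=10.0)
        X = build_design(ev, spec, n_volumes_per_session=60, discard_volumes=0)
        col = X.values[:, X.column_names.index("s1_onset")]
        h, _, t = canonical_hrf(spec)
        vols = np.arange(60) * spec.tr_s
        expected = np.interp(vols - 10.0, t, h, left=0.0, right=0.0)
        peak_vol = np.argmax(col)
        assert abs(vols[peak_vol] - (10.0 + t[np.argmax(h)])) <= spec.tr_s
        np.testing.assert_allclose(col, expected, atol=0.05)

    def test_constant_modulator_column_is_zero(self, subject_events):
        ev = subject_events.copy()
        ev["pstop"] = 0.3  # constant across all trials
        X = build_design(ev, n_volumes_per_session=300)
        for name in X.column_names:
            if name.endswith("GS_pstop"):
                np.testing.assert_allclose(X.values[:, X.column_names.index(name)], 0.0, atol=1e-12)

    def test_antisymmetric_modulator_pair(self):
        spec = HRFSpec()
        rows = []
        for i, (onset, val) in enumerate([(10.0, 0.4), (60.0, 0.2)]):
            r = _single_trial_events(onset=onset, pstop=val).iloc[0].to_dict()
            r["index"] = i + 1
            rows.append(r)
        ev = pd.DataFrame(rows)
        X = build_design(ev, spec, n_volumes_per_session=80, discard_volumes=0)
        col = X.values[:, X.column_names.index("s1_GS_pstop")]
        # mean-centered values are +0.1 / -0.1: the column is the difference
        # of two shifted HRFs scaled by 0.1
        h, _, t = canonical_hrf(spec)
        vols = np.arange(80) * spec.tr_s
        expected = 0.1 * (
            np.interp(vols - 10.0, t, h, left=0.0, right=0.0)
            - np.interp(vols - 60.0, t, h, left=0.0, right=0.0)
        )
        np.testing.assert_allclose(col, expected, atol=0.02)

    def test_empty_stratum_column_omitted(self):
        ev = _single_trial_events()  # GS only: no SS/SE strata
        X = build_design(ev, n_volumes_per_session=60, discard_volumes=0)
        assert not any("SS_" in n or "SE_" in n for n in X.column_names)
        assert any(n.endswith("GS_pstop") for n in X.column_names)

    def test_onset_outside_session_rejected(self):
        ev = _single_trial_events(onset=500.0)
        with pytest.raises(ValueError, match="onset"):
            build_design(ev, n_volumes_per_session=60)

    def test_deterministic(self, subject_events):
        X1 = build_design(subject_events)
        X2 = build_design(subject_events)
        np.testing.assert_array_equal(X1.values, X2.values)
        assert X1.column_names == X2.column_names


class TestFit:
    def test_exact_fit_in_column_space(self, subject_events):
        X = build_design(subject_events)
        beta = np.zeros(len(X.column_names))
        for i, n in enumerate(X.column_names):
            if n.endswith("_onset"):
                beta[i] = 2.0
            if n.endswith("_GS_pstop"):
                beta[i] = 1.0
        fit = fit_glm_ar1(X.values @ beta, X)
        est, _ = contrast(fit, modulator_contrast_weights(X, "GS_pstop"))
        assert est == pytest.approx(1.0, abs=1e-8)
        assert fit.sigma2 == pytest.approx(0.0, abs=1e-16)

    def test_white_noise_rho_near_zero(self):
        X = _toy_design(n=1500, seed=1)
        y = np.random.default_rng(2).normal(size=1500)
        fit = fit_glm_ar1(y, X)
        assert abs(fit.rho) < 0.05

    def test_beta_and_rho_recovery_under_ar1_noise(self):
        X = _toy_design(n=2000, seed=3)
        rng = np.random.default_rng(4)
        beta_true = np.array([1.0, -0.5, 0.25, 3.0])
        e = rng.normal(size=2000)
        for t in range(1, 2000):
            e[t] += 0.3 * e[t - 1]
        fit = fit_glm_ar1(X.values @ beta_true + e, X)
        assert abs(fit.rho - 0.3) < 0.05
        se = np.sqrt(np.diag(fit.cov_betas))
        assert np.all(np.abs(fit.betas - beta_true) < 2.0 * se)

    def test_whitening_with_zero_rho_is_ols(self):
        X = _toy_design(n=400, seed=5)
        y = np.random.default_rng(6).normal(size=400)
        fit = fit_glm_ar1(y, X, rho=0.0)
        ols_beta, *_ = np.linalg.lstsq(X.values, y, rcond=None)
        np.testing.assert_allclose(fit.betas, ols_beta, atol=1e-12)
        assert fit.rho == 0.0

    def test_dct_removes_low_frequency_drift(self, subject_events):
        X = build_design(subject_events)
        rng = np.random.default_rng(8)
        y = rng.normal(size=X.values.shape[0])
        fit0 = fit_glm_ar1(y, X)
        # drift built from the DCT basis itself
        drift = X.dct @ rng.normal(size=X.dct.shape[1]) * 50.0
        fit1 = fit_glm_ar1(y + drift, X)
        w = modulator_contrast_weights(X, "GS_pstop")
        est0, _ = contrast(fit0, w)
        est1, _ = contrast(fit1, w)
        assert est1 == pytest.approx(est0, rel=1e-8, abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        X = _toy_design(n=200, seed=9)
        X.values[:, 1] = X.values[:, 0]
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            fit_glm_ar1(np.zeros(200), X)

    def test_mismatched_lengths_rejected(self):
        X = _toy_design(n=100)
        with pytest.raises(ValueError, match="length"):
            fit_glm_ar1(np.zeros(99), X)


class TestContrast:
    def test_plus_minus_negation(self, subject_events):
        X = build_design(subject_events)
        y = np.random.default_rng(10).normal(size=X.values.shape[0])
        fit = fit_glm_ar1(y, X)
        ep, tp = contrast(fit, modulator_contrast_weights(X, "GS_pstop", +1.0))
        em, tm = contrast(fit, modulator_contrast_weights(X, "GS_pstop", -1.0))
        assert ep == pytest.approx(-em, abs=1e-14)
        assert tp == pytest.approx(-tm, abs=1e-12)

    def test_zero_weights(self):
        X = _toy_design(n=100)
        fit = fit_glm_ar1(np.random.default_rng(11).normal(size=100), X)
        est, t = contrast(fit, np.zeros(4))
        assert est == 0.0 and t == 0.0

    def test_mean_centering_makes_contrast_shift_invariant(self, subject_events):
        """Adding a constant to all modulator values leaves the contrast alone."""
        X0 = build_design(subject_events)
        shifted = subject_events.copy()
        shifted["pstop"] = shifted["pstop"] + 0.2
        X1 = build_design(shifted)
        i0 = [i for i, n in enumerate(X0.column_names) if n.endswith("GS_pstop")]
        np.testing.assert_allclose(X0.values[:, i0], X1.values[:, i0], atol=1e-10)


class TestDCTBasis:
    def test_cutoff_scaling(self):
        b = dct_basis(295, 2.0)
        assert b.shape == (295, int(np.floor(2 * 295 * 2.0 / 128.0)))

    def test_orthonormal_columns(self):
        b = dct_basis(295, 2.0)
        np.testing.assert_allclose(b.T @ b, np.eye(b.shape[1]), atol=1e-10)
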