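"""Dynamic belief model: discretized beta machinery and p(Stop) estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from stopbayes.dbm import (
    BeliefState,
    DBMParams,
    advance_prior,
    best_filter_decay,
    exponential_filter,
    fit_params,
    make_prior,
    pstop,
    run_sequence,
    update_posterior,
)


class TestPrior:
    @pytest.mark.parametrize("pm,scale", [(0.25, 4.0), (0.5, 2.0), (0.1, 10.0)])
    def test_prior_mean_matches_pm(self, pm, scale):
        state = make_prior(DBMParams(pm=pm, scale=scale))
        assert pstop(state) == pytest.approx(pm, abs=0.005)

    def test_symmetric_prior(self):
        state = make_prior(DBMParams(pm=0.5, scale=2.0))
        np.testing.assert_allclose(
            state.predictive_mass, state.predictive_mass[::-1], atol=1e-10
        )

    def test_grid_refinement_converges(self):
        means = [
            pstop(make_prior(DBMParams(pm=0.25, scale=4.0, grid_size=g)))
            for g in (100, 1000)
        ]
        assert abs(means[0] - means[1]) < 0.002

    @pytest.mark.parametrize(
        "kwargs,name",
        [
            ({"alpha": 1.5}, "alpha"),
            ({"alpha": -0.1}, "alpha"),
            ({"pm": 0.0}, "pm"),
            ({"pm": 1.0}, "pm"),
            ({"scale": 0.0}, "scale"),
            ({"grid_size": 5}, "grid_size"),
        ],
    )
    def test_invalid_params_name_the_field(self, kwargs, name):
        with pytest.raises(ValueError, match=name):
            DBMParams(**kwargs)


class TestUpdate:
    def test_stop_on_uniform_gives_beta_2_1_mean(self):
        params = DBMParams(pm=0.5, scale=2.0)  # Beta(1,1) = uniform
        state = update_posterior(make_prior(params), 1)
        post_mean = float(state.r_grid @ state.posterior_mass)
        assert post_mean == pytest.approx(2.0 / 3.0, abs=0.01)

    def test_stop_on_beta_1_3_gives_beta_2_3_mean(self):
        params = DBMParams(pm=0.25, scale=4.0)  # Beta(1,3)
        state = update_posterior(make_prior(params), 1)
        post_mean = float(state.r_grid @ state.posterior_mass)
        assert post_mean == pytest.approx(2.0 / 5.0, abs=0.01)

    def test_go_lowers_the_mean(self):
        state = make_prior(DBMParams())
        updated = update_posterior(state, 0)
        assert float(updated.r_grid @ updated.posterior_mass) < pstop(state)

    def test_invalid_outcome(self):
        with pytest.raises(ValueError, match="outcome"):
            update_posterior(make_prior(DBMParams()), 2)


class TestAdvance:
    def test_alpha_zero_resets_to_prior(self):
        params = DBMParams(alpha=0.0)
        state = advance_prior(update_posterior(make_prior(params), 1), params)
        np.testing.assert_allclose(state.predictive_mass, state.prior_mass, atol=1e-12)

    def test_alpha_one_keeps_posterior(self):
        params = DBMParams(alpha=1.0)
        state = update_posterior(make_prior(params), 1)
        advanced = advance_prior(state, params)
        np.testing.assert_allclose(advanced.predictive_mass, state.posterior_mass, atol=1e-12)

    def test_prior_is_fixed_point(self):
        params = DBMParams(alpha=0.5)
        state = advance_prior(make_prior(params), params)
        np.testing.assert_allclose(state.predictive_mass, state.prior_mass, atol=1e-12)
        assert state.trial_index == 2


class TestRunSequence:
    def test_alpha_zero_is_constant_pm(self, random_sequences):
        for cats in random_sequences[:2]:
            series = run_sequence(cats, DBMParams(alpha=0.0))
            np.testing.assert_allclose(series, series[0], atol=1e-12)
            assert series[0] == pytest.approx(0.25, abs=0.005)

    def test_alpha_one_matches_conjugate_closed_form(self, random_sequences):
        """alpha = 1 never forgets: p(Stop)_k is the Beta-Bernoulli posterior
        predictive (pm*scale + #stops before k) / (scale + k - 1)."""
        pm, scale = 0.25, 4.0
        for cats in random_sequences:
            cats = cats[:500]
            series = run_sequence(cats, DBMParams(alpha=1.0, pm=pm, scale=scale))
            k = np.arange(cats.size)
            stops_before = np.concatenate([[0], np.cumsum(cats)[:-1]])
            closed = (pm * scale + stops_before) / (scale + k)
            np.testing.assert_allclose(series, closed, atol=0.005)

    def test_explicit_conjugate_values(self):
        series = run_sequence([1, 0, 0], DBMParams(alpha=1.0, pm=0.25, scale=4.0))
        np.testing.assert_allclose(series, [0.25, 0.40, 1.0 / 3.0], atol=0.005)

    def test_causality_suffix_permutation(self, random_sequences):
        cats = random_sequences[0].copy()
        series = run_sequence(cats, DBMParams())
        k = 150
        permuted = cats.copy()
        permuted[k:] = permuted[k:][::-1]
        series_p = run_sequence(permuted, DBMParams())
        np.testing.assert_allclose(series[: k + 1], series_p[: k + 1], atol=1e-12)

    def test_stop_raises_next_pstop_above_go(self):
        base = [0, 0, 1, 0, 1]
        after_stop = run_sequence(base + [1, 0], DBMParams())
        after_go = run_sequence(base + [0, 0], DBMParams())
        assert after_stop[-1] > after_go[-1]

    def test_grid_convergence(self, random_sequences):
        cats = random_sequences[1]
        s100 = run_sequence(cats, DBMParams(grid_size=100))
        s200 = run_sequence(cats, DBMParams(grid_size=200))
        assert np.max(np.abs(s100 - s200)) < 0.002

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            run_sequence([], DBMParams())

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=60))
    def test_pstop_always_a_probability(self, cats):
        series = run_sequence(cats, DBMParams())
        assert np.all((series >= 0.0) & (series <= 1.0))

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=40))
    def test_normalization_at_every_step(self, cats):
        params = DBMParams()
        state = make_prior(params)
        for s in cats:
            assert abs(state.predictive_mass.sum() - 1.0) < 1e-10
            state = update_posterior(state, s)
            assert abs(state.posterior_mass.sum() - 1.0) < 1e-10
            state = advance_prior(state, params)


class TestExponentialFilter:
    def test_decay_near_one_approaches_cumulative_fraction(self, random_sequences):
        cats = random_sequences[0]
        series = exponential_filter(cats, 0.9999, init=0.25)
        k = np.arange(cats.size)
        cumfrac = (0.25 + np.concatenate([[0], np.cumsum(cats)[:-1]])) / (1.0 + k)
        np.testing.assert_allclose(series, cumfrac, atol=0.01)

    def test_all_go_decays_toward_zero(self):
        series = exponential_filter(np.zeros(200, dtype=int), 0.9, init=0.4)
        assert series[0] == pytest.approx(0.4)
        assert np.all(np.diff(series) <= 1e-12)
        assert series[-1] < 0.01

    @pytest.mark.parametrize("alpha", [0.6, 0.8, 0.95])
    def test_best_filter_tracks_dbm(self, alpha, random_sequences):
        """The mixture model is approximately an exponential linear filter."""
        cats = random_sequences[2]
        series = run_sequence(cats, DBMParams(alpha=alpha))
        _, r = best_filter_decay(cats, series)
        assert r > 0.95


class TestFitParams:
    def test_recovers_generating_params(self, random_sequences):
        cats = random_sequences[3]
        true = DBMParams(alpha=0.8)
        ps = run_sequence(cats, true)
        rt = 500.0 + 300.0 * ps[cats == 0]  # exact linear readout
        grid = [DBMParams(alpha=a) for a in (0.2, 0.5, 0.8, 0.95)]
        best, r, _ = fit_params(cats, rt, grid)
        assert best == true
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_single_candidate_returned(self, random_sequences):
        cats = random_sequences[0]
        rng = np.random.default_rng(0)
        rt = rng.normal(600, 50, size=int((cats == 0).sum()))
        only = DBMParams(alpha=0.3)
        best, _, _ = fit_params(cats, rt, [only])
        assert best == only

    def test_noise_rt_not_significant_on_average(self, random_sequences):
        """With pure-noise RT the best-grid correlation is flagged as weak."""
        cats = random_sequences[1]
        rng = np.random.default_rng(99)
        pvals = []
        for _ in range(20):
            rt = rng.normal(600, 50, size=int((cats == 0).sum()))
            _, r, p = fit_params(cats, rt, [DBMParams(alpha=0.8)])
            pvals.append(p)
        # around 5% of null fits reach p < 0.05; 20 draws should not mostly do so
        assert np.mean(np.asarray(pvals) < 0.05) < 0.3

    def test_degenerate_rt_rejected(self, random_sequences):
        cats = random_sequences[0]
        with pytest.raises(ValueError, match="variance"):
            fit_params(cats, np.full(int((cats == 0).sum()), 600.0), [DBMParams()])
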