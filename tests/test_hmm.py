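import numpy as np
import pytest

from walkhmm import (
    AngleDist,
    FitResult,
    HMMParams,
    HMMSpec,
    InvalidTrackError,
    MovementHMM,
    Observations,
    SimConfig,
    StepDist,
    Track,
    absolutize,
    angle_logpdf,
    dwell_times,
    forward_loglik,
    observations,
    simulate_track,
    stationary_distribution,
    step_logpdf,
    study_params,
    transition_summary,
    viterbi,
)
from walkhmm.hmm import _make_objective, _pack, _unpack, fit

from oracles import brute_force_loglik, brute_force_viterbi


def small_track(rng, n_positions=5):
    increments = rng.normal(size=(n_positions - 1, 2))
    return Track(id="s", positions=np.vstack([[0, 0], np.cumsum(increments, axis=0)]))


def result_from_path(path, n_states, tpm=None):
    """Minimal FitResult wrapper for summary-function tests."""
    path = np.asarray(path)
    if tpm is None:
        tpm = np.full((n_states, n_states), 1.0 / n_states)
    params = HMMParams(
        angle_dists=tuple(AngleDist(0.0, 1.0) for _ in range(n_states)),
        step_dists=tuple(StepDist(0.5, 0.2) for _ in range(n_states)),
        tpm=tpm,
    )
    return FitResult(params=params, loglik=0.0, n_params=1, n_obs=len(path),
                     aic=0.0, bic=0.0, viterbi_path=path, converged=True)


class TestObservations:
    def test_relative_mode_counts(self, rng):
        obs = observations(small_track(rng, 3), "relative")
        assert obs.n_steps == 2
        assert np.isnan(obs.angles[0]) and np.isfinite(obs.angles[1])

    def test_absolute_mode_counts(self, rng):
        obs = observations(small_track(rng, 3), "absolute")
        assert obs.n_steps == 2
        assert np.all(np.isfinite(obs.angles))

    def test_zero_step_marks_angles_missing(self):
        positions = np.array([[0.0, 0], [1, 0], [1, 0], [2, 1], [3, 1]])
        track = Track(id="z", positions=positions)
        rel = observations(track, "relative")
        assert np.isnan(rel.angles[1]) and np.isnan(rel.angles[2])
        assert not rel.step_included[1]
        ab = observations(track, "absolute")
        assert np.isnan(ab.angles[1]) and np.isfinite(ab.angles[2])

    def test_too_short_for_mode(self, rng):
        with pytest.raises(InvalidTrackError):
            observations(small_track(rng, 2), "relative")
        assert observations(small_track(rng, 2), "absolute").n_steps == 1


class TestForwardLoglik:
    def test_single_state_is_sum_of_logpdfs(self, rng, random_params):
        params = random_params(rng, 1)
        obs = observations(small_track(rng, 10), "relative")
        expected = sum(
            step_logpdf(s, params.step_dists[0]) for s in obs.steps
        ) + sum(
            angle_logpdf(a, params.angle_dists[0])
            for a in obs.angles if np.isfinite(a)
        )
        assert forward_loglik(obs, params) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("n_states,n_positions", [(2, 4), (2, 6), (3, 5)])
    def test_matches_exhaustive_path_enumeration(self, rng, random_params,
                                                 n_states, n_positions):
        params = random_params(rng, n_states)
        for mode in ("relative", "absolute"):
            obs = observations(small_track(rng, n_positions), mode)
            assert forward_loglik(obs, params) == pytest.approx(
                brute_force_loglik(obs, params), rel=1e-10
            )

    def test_state_relabelling_invariance(self, rng, random_params):
        params = random_params(rng, 3)
        obs = observations(small_track(rng, 12), "relative")
        perm = [2, 0, 1]
        permuted = HMMParams(
            angle_dists=tuple(params.angle_dists[i] for i in perm),
            step_dists=tuple(params.step_dists[i] for i in perm),
            tpm=params.tpm[np.ix_(perm, perm)],
        )
        assert forward_loglik(obs, permuted) == pytest.approx(
            forward_loglik(obs, params), rel=1e-10
        )

    def test_missing_angles_contribute_factor_one(self, rng, random_params):
        params = random_params(rng, 2)
        obs = observations(small_track(rng, 6), "relative")
        masked = Observations(steps=obs.steps,
                              angles=np.full_like(obs.angles, np.nan),
                              mode="relative")
        expected = brute_force_loglik(masked, params)
        assert forward_loglik(masked, params) == pytest.approx(expected, rel=1e-10)


class TestViterbi:
    def test_single_state_constant_path(self, rng, random_params):
        params = random_params(rng, 1)
        obs = observations(small_track(rng, 10), "relative")
        assert np.all(viterbi(obs, params) == 0)

    @pytest.mark.parametrize("n_states,n_positions", [(2, 5), (2, 7), (3, 5)])
    def test_matches_brute_force(self, rng, random_params, n_states, n_positions):
        params = random_params(rng, n_states)
        obs = observations(small_track(rng, n_positions), "absolute")
        expected, _ = brute_force_viterbi(obs, params)
        np.testing.assert_array_equal(viterbi(obs, params), expected)

    def test_decodes_well_separated_simulation(self):
        spec, params = study_params(2)
        track = simulate_track(SimConfig(spec=spec, params=params, T=400, seed=11))
        path = viterbi(observations(track, "relative"), params)
        accuracy = np.mean(path == track.true_states)
        assert max(accuracy, 1 - accuracy) >= 0.95


class TestStationaryDistribution:
    def test_solves_fixed_point(self, rng, random_params):
        for n in (2, 3, 4):
            tpm = random_params(rng, n).tpm
            delta = stationary_distribution(tpm)
            np.testing.assert_allclose(delta @ tpm, delta, atol=1e-12)
            assert delta.sum() == pytest.approx(1.0)


class TestKernelFallbacks:
    """The pure-numpy recursion fallbacks must agree with the dispatched
    (possibly numba-compiled) kernels and the brute-force oracle."""

    def test_forward_scaled_numpy_matches_dispatch(self, rng, random_params):
        from walkhmm._core import _forward_scaled_numpy, forward_scaled

        params = random_params(rng, 3)
        p = rng.uniform(0.1, 1.0, size=(15, 3))
        delta = params.initial_distribution()
        assert _forward_scaled_numpy(p, params.tpm, delta) == pytest.approx(
            forward_scaled(p, params.tpm, delta), rel=1e-12
        )

    def test_forward_backward_numpy_matches_dispatch(self, rng, random_params):
        from walkhmm._core import _forward_backward_numpy, forward_backward

        params = random_params(rng, 2)
        logp = rng.normal(size=(12, 2))
        delta = params.initial_distribution()
        ll_np, gamma_np, xi_np = _forward_backward_numpy(logp, params.tpm, delta)
        ll, gamma, xi = forward_backward(logp, params.tpm, delta)
        assert ll_np == pytest.approx(ll, rel=1e-12)
        np.testing.assert_allclose(gamma_np, gamma, atol=1e-12)
        np.testing.assert_allclose(xi_np, xi, atol=1e-12)
        # posteriors are proper distributions; xi totals T-1 transitions
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)
        assert xi.sum() == pytest.approx(len(logp) - 1)


class TestAnalyticGradient:
    @pytest.mark.parametrize("family", ["vonmises", "wrappedcauchy"])
    @pytest.mark.parametrize("n_states", [1, 2, 3])
    def test_matches_finite_differences(self, rng, random_params, family, n_states):
        from scipy.optimize import approx_fprime

        params = random_params(rng, n_states, family=family)
        obs = observations(small_track(rng, 40), "relative")
        objective = _make_objective(obs, n_states, family)
        z = _pack(params, family)
        _, grad = objective(z)
        grad_fd = approx_fprime(z, lambda zz: objective(zz)[0], 1e-6)
        np.testing.assert_allclose(grad, grad_fd, atol=1e-3, rtol=1e-3)

    def test_pack_unpack_roundtrip(self, rng, random_params):
        params = random_params(rng, 3)
        rebuilt = _unpack(_pack(params, "vonmises"), 3, "vonmises")
        np.testing.assert_allclose(rebuilt.tpm, params.tpm, atol=1e-10)
        for a, b in zip(rebuilt.step_dists, params.step_dists):
            assert a.mu_gamma == pytest.approx(b.mu_gamma)


class TestFit:
    def test_one_state_parameter_recovery(self):
        spec, _ = study_params(1)
        truth = HMMParams(
            angle_dists=(AngleDist(mu=0.5, kappa=2.0),),
            step_dists=(StepDist(mu_gamma=0.4, sigma_gamma=0.15),),
            tpm=np.ones((1, 1)),
        )
        track = simulate_track(
            SimConfig(spec=HMMSpec(1), params=truth, T=500, seed=21)
        )
        est = MovementHMM(n_states=1, starts="grid").fit(track)
        a, s = est.params_.angle_dists[0], est.params_.step_dists[0]
        assert a.mu == pytest.approx(0.5, abs=0.1)
        assert a.kappa == pytest.approx(2.0, rel=0.1)
        assert s.mu_gamma == pytest.approx(0.4, rel=0.1)
        assert s.sigma_gamma == pytest.approx(0.15, rel=0.1)

    def test_two_state_loglik_dominates_one_state(self):
        spec, params = study_params(1)
        track = simulate_track(SimConfig(spec=spec, params=params, T=300, seed=5))
        one = MovementHMM(n_states=1, starts="grid").fit(track)
        two = MovementHMM(n_states=2, starts=16).fit(track)
        assert two.loglik_ >= one.loglik_ - 1e-6

    def test_two_state_recovery_well_separated(self):
        spec, params = study_params(2)
        track = simulate_track(SimConfig(spec=spec, params=params, T=500, seed=8))
        est = MovementHMM(n_states=2, starts=16).fit(track)
        means = sorted(d.mu_gamma for d in est.params_.step_dists)
        truth = sorted(d.mu_gamma for d in params.step_dists)
        for m, t in zip(means, truth):
            assert m == pytest.approx(t, rel=0.15)
        assert np.all(np.abs(np.diag(est.params_.tpm) - 0.9) < 0.1)

    def test_states_ordered_by_step_mean(self):
        spec, params = study_params(3)
        track = simulate_track(SimConfig(spec=spec, params=params, T=500, seed=9))
        est = MovementHMM(n_states=3, starts=16).fit(track)
        means = [d.mu_gamma for d in est.params_.step_dists]
        assert means == sorted(means)

    def test_requires_starting_points(self, rng):
        obs = observations(small_track(rng, 20), "relative")
        with pytest.raises(ValueError):
            fit(obs, HMMSpec(1), starts=[])


class TestModeEquivalence:
    def test_absolute_loglik_equals_relative_on_transformed(self, rng,
                                                            random_params,
                                                            make_track):
        track = make_track(rng, n_positions=30)
        params = random_params(rng, 2)
        ll_native = forward_loglik(observations(track, "absolute"), params)
        transformed = absolutize(track)
        ll_via_transform = forward_loglik(
            observations(transformed, "relative", exclude_first_step=True), params
        )
        assert ll_via_transform == pytest.approx(ll_native, abs=1e-8)


class TestTransitionSummary:
    def test_counts_and_occupancy(self):
        res = result_from_path([0, 0, 1, 1, 1], 2)
        tpm, counts, occupancy, unobserved = transition_summary(res)
        np.testing.assert_array_equal(counts, [[1, 1], [0, 2]])
        np.testing.assert_allclose(occupancy, [0.4, 0.6])
        assert occupancy.sum() == pytest.approx(1.0)
        np.testing.assert_array_equal(unobserved, counts == 0)


class TestDwellTimes:
    def test_run_length_means(self):
        res = result_from_path([0, 0, 0, 1, 1, 0], 2)
        np.testing.assert_allclose(dwell_times(res, "viterbi_runs"), [2.0, 2.0])

    def test_geometric_from_diagonal(self):
        res = result_from_path([0, 1], 2, tpm=np.array([[0.9, 0.1], [0.3, 0.7]]))
        np.testing.assert_allclose(dwell_times(res, "geometric"),
                                   [10.0, 1.0 / 0.3])

    def test_unvisited_state_is_missing(self):
        res = result_from_path([0, 0, 0], 2)
        dwell = dwell_times(res, "viterbi_runs")
        assert dwell[0] == 3.0 and np.isnan(dwell[1])

    def test_methods_agree_on_long_simulated_path(self):
        spec, params = study_params(2)
        track = simulate_track(SimConfig(spec=spec, params=params, T=3000, seed=13))
        est = MovementHMM(n_states=2, starts=8).fit(track)
        runs = dwell_times(est.result_, "viterbi_runs")
        geo = dwell_times(est.result_, "geometric")
        np.testing.assert_allclose(runs, geo, rtol=0.2)


class TestSklearnInterface:
    def test_get_set_params_roundtrip(self):
        est = MovementHMM(n_states=3, angle_mode="absolute")
        params = est.get_params()
        clone = MovementHMM().set_params(**params)
        assert clone.get_params() == params

    def test_invalid_param_rejected(self):
        with pytest.raises(ValueError):
            MovementHMM().set_params(bogus=1)

    def test_predict_before_fit_raises(self, rng):
        with pytest.raises(RuntimeError):
            MovementHMM().predict(small_track(rng, 10))

    def test_fit_predict_score(self):
        spec, params = study_params(2)
        track = simulate_track(SimConfig(spec=spec, params=params, T=200, seed=3))
        est = MovementHMM(n_states=2, starts=4).fit(track)
        path = est.predict(track)
        np.testing.assert_array_equal(path, est.viterbi_path_)
        assert est.score(track) == pytest.approx(est.loglik_)
        assert est.bic_ == pytest.approx(
            -2 * est.loglik_ + est.n_params_ * np.log(est.n_obs_)
        )
        assert est.aic_ == pytest.approx(-2 * est.loglik_ + 2 * est.n_params_)
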