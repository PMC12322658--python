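"""Fit objective, particle swarm, per-condition estimation, training sets."""

import numpy as np
import pytest

from optoferm import (
    Condition,
    FitProblem,
    FitResult,
    KineticParams,
    PSOSettings,
    StateVector,
    build_training_set,
    fit_condition,
    fit_objective,
    pso_minimize,
    simulate,
)
from optoferm.model import PARAM_NAMES


def _problem_from_params(params, condition=Condition(10.0, 1), noise=None, seed=0,
                         replicates=1, **kwargs):
    times = np.array([0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 15.0, 24.0])
    init = StateVector(c_b=0.1, c_p=0.0, c_g=10.0, n=condition.copy_number)
    # same tolerances the fit objective integrates with, so hand-set
    # offsets translate into residuals exactly
    traj = simulate(init, params, times, rtol=1e-6, atol=1e-9)
    rng = np.random.default_rng(seed)
    obs = {}
    for r in range(replicates):
        od, prot = traj.c_b.copy(), traj.c_p.copy()
        if noise:
            od = od * np.exp(noise * rng.standard_normal(times.size))
            prot = prot * np.exp(noise * rng.standard_normal(times.size))
        obs[r] = {"times": times, "od": od, "protein": prot}
    return FitProblem(observations=obs, initial_glucose=10.0, condition=condition,
                      **kwargs)


class TestFitObjective:
    def test_zero_on_self_consistent_data(self, params):
        prob = _problem_from_params(params)
        assert fit_objective(params, prob) < 1e-10

    def test_positive_after_perturbation(self, params):
        prob = _problem_from_params(params)
        worse = KineticParams(1.5 * params.mu_max, params.k_g, params.alpha,
                              params.beta, params.d_p, params.y_gb)
        assert fit_objective(worse, prob) > 1e-4

    def test_hand_computed_weighted_sum(self, params):
        """Known per-point offsets reproduce the stated relative-weighting
        formula: sum(residual^2)/mean-square(observed), per channel.
        The protein channel is shifted at every point and the OD channel
        everywhere except t0 (the initial OD is read from the data, so a
        t0 shift would move the simulation start instead)."""
        prob = _problem_from_params(params)
        obs = prob.observations[0]
        od_off, prot_off = 0.05, 30.0
        od = obs["od"].copy()
        od[1:] += od_off
        shifted = {0: {"times": obs["times"], "od": od,
                       "protein": obs["protein"] + prot_off}}
        prob2 = FitProblem(observations=shifted, initial_glucose=10.0,
                           condition=prob.condition)
        n = obs["times"].size
        expected = (
            (n - 1) * od_off**2 / np.mean(od**2)
            + n * prot_off**2 / np.mean((obs["protein"] + prot_off) ** 2)
        )
        assert fit_objective(params, prob2) == pytest.approx(expected, rel=1e-6)

    def test_channel_weights_scale_contributions(self, params):
        prob = _problem_from_params(params)
        obs = prob.observations[0]
        shifted = {0: {"times": obs["times"], "od": obs["od"],
                       "protein": obs["protein"] + 40.0}}
        base = FitProblem(observations=shifted, initial_glucose=10.0,
                          condition=prob.condition)
        doubled = FitProblem(observations=shifted, initial_glucose=10.0,
                             condition=prob.condition,
                             weights={"od": 1.0, "protein": 2.0})
        assert fit_objective(params, doubled) == pytest.approx(
            2 * fit_objective(params, base), rel=1e-6)

    def test_solver_failure_maps_to_inf(self, params, monkeypatch):
        import optoferm.calibration as cal
        from optoferm.model import SimulationError

        prob = _problem_from_params(params)

        def boom(*a, **kw):
            raise SimulationError("synthetic failure", time=0.0)

        monkeypatch.setattr(cal, "simulate", boom)
        assert cal.fit_objective(params, prob) == np.inf


class TestPSO:
    def test_sphere_minimum_located(self):
        bounds = np.array([[-5.0, 5.0], [-5.0, 5.0]])
        res = pso_minimize(lambda x: float(x @ x), bounds,
                           PSOSettings(swarm_size=30, iterations=200, seed=0))
        assert np.all(np.abs(res.x) < 1e-3)

    def test_rosenbrock_converges(self):
        def rosen(x):
            return float(100 * (x[1] - x[0] ** 2) ** 2 + (1 - x[0]) ** 2)

        bounds = np.array([[-2.0, 2.0], [-1.0, 3.0]])
        res = pso_minimize(rosen, bounds,
                           PSOSettings(swarm_size=40, iterations=500, seed=1))
        assert res.fun <= 1e-2

    def test_zero_coefficients_return_best_start(self):
        bounds = np.array([[-1.0, 1.0]] * 2)
        settings = PSOSettings(swarm_size=5, iterations=10, inertia=0.0,
                               cognitive=0.0, social=0.0, seed=3)
        rng = np.random.default_rng(3)
        starts = rng.uniform(bounds[:, 0], bounds[:, 1], size=(5, 2))
        res = pso_minimize(lambda x: float(x @ x), bounds, settings)
        best_start = min(starts, key=lambda x: float(x @ x))
        assert res.fun == pytest.approx(float(best_start @ best_start))

    def test_deterministic_for_fixed_seed(self):
        bounds = np.array([[-5.0, 5.0]] * 3)
        s = PSOSettings(swarm_size=12, iterations=50, seed=7)
        f = lambda x: float(np.sum(x**2) + np.sin(5 * x[0]))
        a = pso_minimize(f, bounds, s)
        b = pso_minimize(f, bounds, s)
        assert np.array_equal(a.x, b.x)
        assert a.fun == b.fun

    def test_global_best_trace_nonincreasing(self):
        bounds = np.array([[-5.0, 5.0]] * 2)
        res = pso_minimize(lambda x: float(x @ x), bounds,
                           PSOSettings(swarm_size=10, iterations=80, seed=2))
        assert np.all(np.diff(res.trace) <= 0)

    def test_nan_objective_treated_as_inf(self):
        def holey(x):
            return np.nan if x[0] > 0 else float(x @ x)

        bounds = np.array([[-2.0, 2.0]] * 2)
        res = pso_minimize(holey, bounds, PSOSettings(swarm_size=10, iterations=40, seed=0))
        assert np.isfinite(res.fun)
        assert res.x[0] <= 0

    def test_tiny_swarm_rejected(self):
        with pytest.raises(ValueError):
            PSOSettings(swarm_size=1)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            pso_minimize(lambda x: 0.0, np.array([[1.0, 1.0]]), PSOSettings())


class TestFitCondition:
    def test_recovers_truth_from_noise_free_data(self, truth_surface):
        cond = Condition(10.0, 3)
        truth = truth_surface.params_at(cond)
        prob = _problem_from_params(truth, condition=cond)
        res = fit_condition(prob, PSOSettings(swarm_size=16, iterations=60, seed=4))
        assert res.objective_value < 1e-6
        for name in ("mu_max", "alpha", "y_gb"):
            assert getattr(res.params, name) == pytest.approx(
                getattr(truth, name), rel=0.05)

    def test_invalid_bounds_raise(self, params):
        with pytest.raises(ValueError):
            _problem_from_params(params, bounds={**{n: (0.1, 1.0) for n in PARAM_NAMES},
                                                 "alpha": (5.0, 2.0)})


def _fake_results(conditions):
    out = []
    for i, (I, n) in enumerate(conditions):
        p = KineticParams(0.3 + 0.001 * i, 0.5, 2e4 + 100 * i, 0.05, 0.02, 0.55)
        out.append(FitResult(params=p, objective_value=0.01, n_evaluations=100,
                             seed=0, converged=True, condition=Condition(I, n)))
    return out


class TestTrainingSet:
    def test_full_design_shapes(self):
        conds = [(I, n) for n in (1, 3, 8) for I in (0, 5, 10, 30, 50, 70)]
        sets = build_training_set(_fake_results(conds))
        assert set(sets) == set(PARAM_NAMES)
        for ts in sets.values():
            assert ts.V.shape == (2, 18)
            assert ts.L.shape == (18,)

    def test_single_condition_rejected(self):
        with pytest.raises(ValueError):
            build_training_set(_fake_results([(10.0, 1)]))

    def test_order_independence(self):
        conds = [(I, n) for n in (1, 8) for I in (0, 30, 70)]
        a = build_training_set(_fake_results(conds))
        flipped = _fake_results(conds)[::-1]
        b = build_training_set(flipped)
        np.testing.assert_array_equal(a["alpha"].V, b["alpha"].V)

    def test_duplicate_conditions_kept_with_warning(self):
        results = _fake_results([(10.0, 1), (10.0, 1), (30.0, 1)])
        with pytest.warns(UserWarning, match="duplicate"):
            sets = build_training_set(results)
        assert sets["mu_max"].nd == 3
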