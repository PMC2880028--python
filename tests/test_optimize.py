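"""Local, multistart, SRES and hybrid optimizers on analytic and fixture problems."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kincal import (
    ParameterSpace,
    ParameterSpec,
    SresConfig,
    hybrid_fit,
    local_fit,
    multistart_fit,
    sres_fit,
    stochastic_ranking,
)
from kincal.parameter_space import GridSizeError


def box_space(d, lower=0.1, upper=10.0):
    nominal = float(np.sqrt(lower * upper))
    return ParameterSpace(
        [ParameterSpec(f"x{j}", nominal, tier=None, lower=lower, upper=upper)
         for j in range(d)]
    )


def quadratic_log(target_log=None):
    """Convex objective in log10 coordinates with a known minimizer."""

    def fun(p):
        z = np.log10(p)
        t = np.zeros_like(z) if target_log is None else target_log
        return float(np.sum((z - t) ** 2))

    return fun


class TestLocalFit:
    def test_convex_objective_reaches_minimum(self):
        space = box_space(1)
        fun = lambda p: (p[0] - 3.0) ** 2
        fit = local_fit(np.array([1.0]), fun, space)
        assert fit.converged
        assert fit.parameters["x0"] == pytest.approx(3.0, rel=1e-4)
        assert fit.objective_value == pytest.approx(0.0, abs=1e-7)

    def test_minimum_at_active_bound(self):
        space = box_space(1)
        fun = lambda p: (np.log10(p[0]) - 5.0) ** 2  # minimum beyond upper bound
        fit = local_fit(np.array([10.0]), fun, space)
        assert fit.converged
        assert fit.parameters["x0"] == pytest.approx(10.0, rel=1e-9)

    def test_failed_start_returns_nonconverged(self):
        space = box_space(2)
        fit = local_fit(np.array([1.0, 1.0]), lambda p: float("inf"), space)
        assert not fit.converged
        assert fit.n_evaluations == 1

    def test_objective_value_matches_parameters(self):
        space = box_space(2)
        fun = quadratic_log()
        fit = local_fit(np.array([5.0, 0.2]), fun, space)
        assert fit.objective_value == pytest.approx(
            fun(np.array([fit.parameters["x0"], fit.parameters["x1"]])), rel=1e-9)


class TestMultistart:
    def test_grid_start_count(self):
        space = box_space(2)
        res = multistart_fit(quadratic_log(), space, levels=3)
        assert len(res.results) == 9

    def test_eight_parameters_three_levels_attempts_6561(self):
        # enumeration-only check: objective is trivial so starts are cheap
        space = box_space(8)
        res = multistart_fit(quadratic_log(), space, levels=3,
                             maxiter=1)
        assert len(res.results) == 6561

    def test_convex_all_starts_agree(self):
        space = box_space(2)
        res = multistart_fit(quadratic_log(), space, levels=3)
        sorted_f = res.sorted_objectives()
        assert sorted_f[-1] - sorted_f[0] < 1e-6
        assert np.all(np.diff(sorted_f) >= 0)

    def test_cap_refusal_propagates(self):
        space = box_space(10)
        with pytest.raises(GridSizeError):
            multistart_fit(quadratic_log(), space, levels=3, cap=100)


class TestStochasticRanking:
    def test_zero_pressure_no_constraints_sorts_objectives(self):
        rng = np.random.default_rng(0)
        f = rng.uniform(0, 10, 40)
        order = stochastic_ranking(f, np.zeros(40), pressure=0.0, rng=rng)
        assert np.all(np.diff(f[order]) >= 0)

    def test_all_feasible_sorts_regardless_of_pressure(self):
        rng = np.random.default_rng(1)
        f = rng.uniform(0, 10, 30)
        order = stochastic_ranking(f, np.zeros(30), pressure=0.45, rng=rng)
        assert np.all(np.diff(f[order]) >= 0)

    def test_zero_pressure_with_constraints_sorts_by_violation(self):
        # with P_f = 0 infeasible candidates are ordered purely by violation
        f = np.array([0.0, 1.0, 2.0, 3.0])
        g = np.array([3.0, 2.0, 1.0, 0.5])
        rng = np.random.default_rng(2)
        order = stochastic_ranking(f, g, pressure=0.0, rng=rng)
        assert list(order) == [3, 2, 1, 0]

    def test_feasible_preferred_over_infeasible_at_zero_pressure(self):
        f = np.array([5.0, 0.1])
        g = np.array([0.0, 4.0])
        rng = np.random.default_rng(3)
        order = stochastic_ranking(f, g, pressure=0.0, rng=rng)
        assert order[0] == 0


class TestSres:
    def test_sphere_benchmark(self):
        space = box_space(2, lower=1e-5, upper=1e5)
        cfg = SresConfig(population_size=40, parents=6, max_generations=100,
                         seed=1, stop_factor=1e12)
        fit = sres_fit(quadratic_log(), space, cfg)
        assert fit.objective_value < 1e-3
        assert np.all(np.diff(fit.trace) <= 0)

    def test_seeded_determinism_bit_identical(self):
        space = box_space(3)
        cfg = SresConfig(population_size=30, parents=5, max_generations=10,
                         seed=7)
        a = sres_fit(quadratic_log(), space, cfg)
        b = sres_fit(quadratic_log(), space, cfg)
        assert a.objective_value == b.objective_value
        assert a.trace == b.trace
        assert a.parameters == b.parameters

    def test_stop_rule_hundredfold_decline(self):
        space = box_space(2)
        cfg = SresConfig(population_size=30, parents=5, max_generations=500,
                         seed=2, stop_factor=100.0)
        fit = sres_fit(quadratic_log(), space, cfg)
        assert len(fit.trace) < 500
        assert fit.trace[-1] <= fit.trace[0] / 100.0

    def test_bound_respect(self):
        space = box_space(2)
        seen = []

        def recording(p):
            seen.append(p.copy())
            return quadratic_log()(p)

        cfg = SresConfig(population_size=20, parents=4, max_generations=15,
                         seed=5, stop_factor=1e12)
        sres_fit(recording, space, cfg)
        assert space.contains(np.array(seen))

    def test_constraint_handling_finds_feasible_optimum(self):
        # minimize (log x - 0.5)^2 subject to log x <= 0: optimum at bound
        space = box_space(1, lower=0.01, upper=100.0)
        fun = lambda p: (np.log10(p[0]) - 0.5) ** 2
        con = lambda p: max(0.0, np.log10(p[0]))
        cfg = SresConfig(population_size=60, parents=10, max_generations=60,
                         seed=9, stop_factor=1e12)
        fit = sres_fit(fun, space, cfg, constraints=con)
        assert np.log10(fit.parameters["x0"]) <= 1e-6
        assert fit.objective_value == pytest.approx(0.25, abs=0.05)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SresConfig(population_size=10, parents=10)
        with pytest.raises(ValueError):
            SresConfig(ranking_pressure=0.7)


class TestHybrid:
    def test_convex_matches_local_regardless_of_seed(self):
        space = box_space(2)
        fun = quadratic_log(np.array([0.3, -0.2]))
        cfg = SresConfig(population_size=20, parents=4, max_generations=5,
                         seed=11, stop_factor=1e12)
        fit = hybrid_fit(fun, space, cfg)
        assert fit.objective_value == pytest.approx(0.0, abs=1e-8)
        assert fit.parameters["x0"] == pytest.approx(10**0.3, rel=1e-3)

    def test_refinement_never_worse_than_global_phase(self):
        space = box_space(3)
        fun = quadratic_log()
        cfg = SresConfig(population_size=20, parents=4, max_generations=5,
                         seed=13, stop_factor=1e12)
        sres_only = sres_fit(fun, space, cfg)
        hybrid = hybrid_fit(fun, space, cfg)
        assert hybrid.objective_value <= sres_only.objective_value

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(seed=st.integers(0, 1000))
    def test_hybrid_trace_monotone(self, seed):
        space = box_space(2)
        cfg = SresConfig(population_size=16, parents=4, max_generations=6,
                         seed=seed, stop_factor=1e12)
        fit = hybrid_fit(quadratic_log(), space, cfg)
        assert np.all(np.diff(fit.trace) <= 1e-12)
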