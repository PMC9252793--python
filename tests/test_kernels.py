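"""Reference kernels: closed forms, conservation, stochastic laws, determinism."""

import math

import numpy as np
import pytest
from scipy import stats

from simex import kernels
from simex._errors import SimexError
from simex.model_io import Parameter, Reaction, ReactionNetworkModel, Species, parse_boolnet
from simex.expressions import MathExpression
from simex.synthetic_models import (
    GeneratorConfig,
    decay_model,
    immigration_death_model,
    isomerization_model,
    production_decay_model,
    random_boolean_network,
    toggle_boolean_model,
)
from simex.conformance import boolean_truth_table_trajectory

RK4 = kernels.KernelConfig(algorithm=kernels.KISAO_RK4)


class TestOde:
    def test_decay_matches_closed_form(self):
        result = kernels.simulate_ode(decay_model(), 0.0, 0.0, 4.0, 4, RK4)
        assert result.row("S1")[-1] == pytest.approx(10.0 * math.exp(-2.0), abs=1e-4)

    def test_zero_reactions_is_constant(self):
        model = ReactionNetworkModel(species=[Species("A", 3.0)])
        result = kernels.simulate_ode(model, 0.0, 0.0, 5.0, 5, RK4)
        assert np.all(result.values == 3.0)

    def test_mass_conservation(self):
        result = kernels.simulate_ode(decay_model(), 0.0, 0.0, 10.0, 20, RK4)
        totals = result.row("S1") + result.row("S2")
        assert np.all(np.abs(totals - 10.0) < 1e-9)

    def test_rk4_is_fourth_order(self):
        """Halving the step shrinks the decay error by at least 8x."""
        errors = []
        for h in (0.01, 0.005):
            config = kernels.KernelConfig(algorithm=kernels.KISAO_RK4, step_size=h)
            result = kernels.simulate_ode(decay_model(), 0.0, 0.0, 10.0, 10, config)
            exact = 10.0 * np.exp(-0.5 * result.times)
            errors.append(np.max(np.abs(result.row("S1") - exact)))
        assert errors[0] / errors[1] >= 8.0

    def test_euler_converges_linearly(self):
        config = kernels.KernelConfig(algorithm=kernels.KISAO_EULER, step_size=0.001)
        result = kernels.simulate_ode(decay_model(), 0.0, 0.0, 4.0, 4, config)
        assert result.row("S1")[-1] == pytest.approx(10.0 * math.exp(-2.0), rel=1e-3)

    def test_output_window_offset(self):
        result = kernels.simulate_ode(decay_model(), 0.0, 2.0, 4.0, 2, RK4)
        assert result.times.tolist() == [2.0, 3.0, 4.0]
        assert result.row("S1")[0] == pytest.approx(10.0 * math.exp(-1.0), abs=1e-6)


class TestSteadyState:
    def test_production_decay_balance(self):
        state = kernels.solve_steady_state(production_decay_model(), kernels.KernelConfig())
        assert state[0] == pytest.approx(4.0, abs=1e-6)

    def test_zero_reaction_model_returns_initial_state(self):
        model = ReactionNetworkModel(species=[Species("A", 2.0)])
        assert kernels.solve_steady_state(model, kernels.KernelConfig()).tolist() == [2.0]

    def test_unbounded_model_never_converges(self):
        model = ReactionNetworkModel(
            species=[Species("S1", 0.0)],
            reactions=[Reaction("J", (), (("S1", 1),), MathExpression.num(1.0))],
        )
        with pytest.raises(SimexError) as err:
            kernels.solve_steady_state(model, kernels.KernelConfig(t_max=100.0))
        assert err.value.code == "NO_CONVERGENCE"


class TestSsa:
    def test_same_seed_same_trajectory(self):
        config = kernels.KernelConfig(algorithm=kernels.KISAO_GILLESPIE, seed=7)
        a = kernels.simulate_ssa(isomerization_model(), 0, 0, 5, 10, config)
        b = kernels.simulate_ssa(isomerization_model(), 0, 0, 5, 10, config)
        assert np.array_equal(a.values, b.values)

    def test_pure_death_mean(self):
        """Linear death process: E[X(1)] = 20 e^-1, checked to 3 standard errors."""
        model = ReactionNetworkModel(
            species=[Species("X", 20.0)],
            parameters=[Parameter("k", 1.0)],
            reactions=[Reaction("J", (("X", 1),), (), MathExpression.parse("k * X"))],
        )
        finals = []
        for seed in range(500):
            config = kernels.KernelConfig(algorithm=kernels.KISAO_GILLESPIE, seed=seed)
            finals.append(kernels.simulate_ssa(model, 0, 0, 1, 1, config).row("X")[-1])
        finals = np.asarray(finals)
        expected = 20.0 * math.exp(-1.0)
        se = finals.std(ddof=1) / math.sqrt(len(finals))
        assert abs(finals.mean() - expected) < 3 * se

    def test_two_state_molecule_matches_markov_law(self):
        """X <-> Y with unit rates, one molecule: P(X=1 at t) = (1+e^-2t)/2."""
        t_end = 0.7
        p = 0.5 * (1.0 + math.exp(-2.0 * t_end))
        n = 3000
        hits = 0
        for seed in range(n):
            config = kernels.KernelConfig(algorithm=kernels.KISAO_GILLESPIE, seed=seed)
            result = kernels.simulate_ssa(isomerization_model(x0=1.0), 0, 0, t_end, 1, config)
            hits += int(result.row("X")[-1] == 1.0)
        observed = [hits, n - hits]
        expected = [n * p, n * (1 - p)]
        chi2 = sum((o - e) ** 2 / e for o, e in zip(observed, expected))
        assert chi2 < stats.chi2.ppf(0.999, df=1)

    def test_non_mass_action_rate_falls_back_with_warning(self):
        model = ReactionNetworkModel(
            species=[Species("X", 5.0)],
            parameters=[Parameter("k", 1.0)],
            reactions=[
                Reaction("J", (("X", 1),), (), MathExpression.parse("k * X / (1 + X)"))
            ],
        )
        config = kernels.KernelConfig(algorithm=kernels.KISAO_GILLESPIE, seed=1)
        result = kernels.simulate_ssa(model, 0, 0, 2, 4, config)
        assert result.warnings
        assert result.row("X")[-1] <= 5.0

    def test_non_integer_initial_amounts_rejected(self):
        model = ReactionNetworkModel(
            species=[Species("X", 2.5)],
            parameters=[Parameter("k", 1.0)],
            reactions=[Reaction("J", (("X", 1),), (), MathExpression.parse("k * X"))],
        )
        with pytest.raises(SimexError) as err:
            kernels.simulate_ssa(model, 0, 0, 1, 1, kernels.KernelConfig())
        assert err.value.code == "BAD_CONFIG"


class TestBoolean:
    def test_toggle_is_a_period_four_cycle(self):
        result = kernels.simulate_boolean(toggle_boolean_model(), 4, "synchronous")
        states = [tuple(result.values[:, k].astype(int)) for k in range(5)]
        assert states == [(1, 1), (0, 1), (0, 0), (1, 0), (1, 1)]

    def test_fixed_point_stays_fixed(self):
        model = parse_boolnet(b"targets, factors\nA, A\n# init: A=1\n")
        result = kernels.simulate_boolean(model, 5, "synchronous")
        assert np.all(result.values == 1.0)

    def test_asynchronous_is_seed_deterministic(self):
        model = random_boolean_network(GeneratorConfig(seed=3))
        a = kernels.simulate_boolean(model, 20, "asynchronous", seed=9)
        b = kernels.simulate_boolean(model, 20, "asynchronous", seed=9)
        assert np.array_equal(a.values, b.values)

    def test_synchronous_matches_truth_table_enumeration(self):
        for seed in range(10):
            model = random_boolean_network(GeneratorConfig(seed=seed))
            expected = boolean_truth_table_trajectory(model, 12)
            result = kernels.simulate_boolean(model, 12, "synchronous")
            assert np.array_equal(result.values, expected)
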