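"""Reference simulation kernels.

Three backends, one per modeling framework:

* deterministic kinetics — fixed-step forward Euler and classic RK4 on the
  stoichiometry-derived vector field dx_i/dt = sum_r nu_ir * rate_r(x, p);
* discrete-stochastic kinetics — the Gillespie direct method (exponential
  waiting times, propensity-proportional reaction choice) on mass-action
  propensities, recorded onto the uniform output grid by zero-order hold;
* logical — synchronous (all nodes at once) or asynchronous (one uniformly
  chosen node per step) Boolean updates.

All kernels are fully determined by their configuration: seeded runs are
bitwise reproducible, and an unseeded stochastic run uses seed 0 rather
than wall-clock entropy so archives without an explicit seed still
reproduce.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from ._errors import SimexError
from .expressions import MathExpression
from .model_io import BooleanNetworkModel, ReactionNetworkModel

KISAO_EULER = "KISAO:0000030"
KISAO_RK4 = "KISAO:0000032"
KISAO_GILLESPIE = "KISAO:0000029"
KISAO_SYNC = "KISAO:0000449"
KISAO_ASYNC = "KISAO:0000450"

#: algorithms the reference kernels implement exactly
IMPLEMENTED_ALGORITHMS = frozenset(
    {KISAO_EULER, KISAO_RK4, KISAO_GILLESPIE, KISAO_SYNC, KISAO_ASYNC}
)


@dataclass
class KernelConfig:
    """Algorithm id plus numeric knobs shared by the kernels.

    ``step_size`` is the internal integrator step (default: a 10,000th of the
    full simulated interval); ``abs_tol`` doubles as the steady-state
    derivative threshold; ``seed`` drives every stochastic choice.
    """

    algorithm: str = KISAO_RK4
    step_size: Optional[float] = None
    rel_tol: float = 1e-6
    abs_tol: float = 1e-8
    seed: Optional[int] = None
    t_max: float = 1e4

    def check(self) -> None:
        if self.step_size is not None and self.step_size <= 0:
            raise SimexError("BAD_CONFIG", "step size must be positive")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise SimexError("BAD_CONFIG", "tolerances must be positive")
        if self.seed is not None and self.seed < 0:
            raise SimexError("BAD_CONFIG", "seed must be nonnegative")
        if self.t_max <= 0:
            raise SimexError("BAD_CONFIG", "t_max must be positive")


@dataclass
class TrajectoryResult:
    """Recorded trajectory: a time grid plus one row per observable."""

    times: np.ndarray
    values: np.ndarray  # shape (n_observables, n_times)
    observable_ids: List[str]
    warnings: List[str] = field(default_factory=list)

    def row(self, observable_id: str) -> np.ndarray:
        try:
            return self.values[self.observable_ids.index(observable_id)]
        except ValueError:
            raise SimexError("MISSING_VARIABLE", f"no observable {observable_id!r}")


# ---------------------------------------------------------------------------
# Deterministic kinetics


def _compile_rates(model: ReactionNetworkModel):
    """Rate callables over a shared mutable env, plus the stoichiometry matrix."""
    index = {s.id: i for i, s in enumerate(model.species)}
    n = len(model.species)
    nu = np.zeros((n, len(model.reactions)))
    for j, reaction in enumerate(model.reactions):
        for sid, stoich in reaction.reactants:
            nu[index[sid], j] -= stoich
        for sid, stoich in reaction.products:
            nu[index[sid], j] += stoich
    env: Dict[str, float] = {p.id: p.value for p in model.parameters}
    rate_fns = [r.rate.compile() for r in model.reactions]
    species_ids = [s.id for s in model.species]

    def derivative(x: np.ndarray) -> np.ndarray:
        for i, sid in enumerate(species_ids):
            env[sid] = x[i]
        rates = np.array([fn(env) for fn in rate_fns], dtype=float)
        return nu @ rates

    return derivative, index, nu, env, rate_fns


def _ode_step(algorithm: str):
    if algorithm == KISAO_EULER:
        def step(f, x, h):
            return x + h * f(x)
    elif algorithm == KISAO_RK4:
        def step(f, x, h):
            k1 = f(x)
            k2 = f(x + 0.5 * h * k1)
            k3 = f(x + 0.5 * h * k2)
            k4 = f(x + h * k3)
            return x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    else:
        raise SimexError("BAD_CONFIG", f"{algorithm} is not a deterministic kernel algorithm")
    return step


def _integrate_to(step, f, x, t_from, t_to, h):
    """Advance with fixed steps, subdividing so the endpoint is hit exactly."""
    span = t_to - t_from
    if span <= 0:
        return x
    n_sub = max(1, math.ceil(span / h - 1e-12))
    h_eff = span / n_sub
    for _ in range(n_sub):
        x = step(f, x, h_eff)
    return x


def simulate_ode(
    model: ReactionNetworkModel,
    t0: float,
    t_start: float,
    t_end: float,
    n_points: int,
    config: KernelConfig,
) -> TrajectoryResult:
    """Integrate a reaction network, recording ``n_points + 1`` uniform points."""
    config.check()
    if not (t0 <= t_start <= t_end):
        raise SimexError("BAD_CONFIG", "need t0 <= t_start <= t_end")
    if n_points < 1:
        raise SimexError("BAD_CONFIG", "n_points must be >= 1")
    step = _ode_step(config.algorithm)
    derivative, _, _, _, _ = _compile_rates(model)
    h = config.step_size or max((t_end - t0), 1e-12) / 10_000.0
    x = np.array([s.initial_amount for s in model.species], dtype=float)
    times = np.linspace(t_start, t_end, n_points + 1)
    values = np.empty((len(model.species), n_points + 1))
    x = _integrate_to(step, derivative, x, t0, t_start, h)
    values[:, 0] = x
    for k in range(1, n_points + 1):
        x = _integrate_to(step, derivative, x, times[k - 1], times[k], h)
        if not np.all(np.isfinite(x)):
            raise SimexError("NONFINITE_STATE", f"state diverged near t={times[k]}")
        values[:, k] = x
    return TrajectoryResult(times, values, [s.id for s in model.species])


def solve_steady_state(model: ReactionNetworkModel, config: KernelConfig) -> np.ndarray:
    """Integrate until ||dx/dt||_inf < abs_tol; raise NO_CONVERGENCE at t_max."""
    config.check()
    step = _ode_step(config.algorithm if config.algorithm in (KISAO_EULER, KISAO_RK4) else KISAO_RK4)
    derivative, _, _, _, _ = _compile_rates(model)
    x = np.array([s.initial_amount for s in model.species], dtype=float)
    if x.size == 0 or not model.reactions:
        return x
    h = config.step_size or 0.1
    t = 0.0
    check_every = 50
    while t < config.t_max:
        for _ in range(check_every):
            x = step(derivative, x, h)
        t += check_every * h
        if not np.all(np.isfinite(x)):
            raise SimexError("NO_CONVERGENCE", "state diverged before reaching steady state")
        if np.max(np.abs(derivative(x))) < config.abs_tol:
            return x
    raise SimexError("NO_CONVERGENCE", f"no steady state within t_max={config.t_max}")


# ---------------------------------------------------------------------------
# Stochastic kinetics (Gillespie direct method)


def _mass_action_constant(
    reaction, param_values: Dict[str, float]
) -> Optional[float]:
    """If the rate is (constants * reactant species matching stoichiometry),
    return the rate constant c; otherwise None."""
    factors: List[MathExpression] = []

    def flatten(expr: MathExpression) -> bool:
        node = expr.node
        if node[0] == "call" and node[1] == "times":
            return all(flatten(arg) for arg in node[2])
        factors.append(expr)
        return True

    flatten(reaction.rate)
    c = 1.0
    species_factors: List[str] = []
    for factor in factors:
        node = factor.node
        if node[0] == "num":
            c *= node[1]
        elif node[0] == "sym" and node[1] in param_values:
            c *= param_values[node[1]]
        elif node[0] == "sym":
            species_factors.append(node[1])
        elif node[0] == "call" and node[1] == "power":
            base, expo = node[2]
            if base.node[0] == "sym" and base.node[1] not in param_values and expo.node[0] == "num":
                k = expo.node[1]
                if k != int(k) or k < 1:
                    return None
                species_factors.extend([base.node[1]] * int(k))
            else:
                return None
        else:
            return None
    expected = []
    for sid, stoich in reaction.reactants:
        expected.extend([sid] * stoich)
    if sorted(species_factors) != sorted(expected):
        return None
    return c


def _falling_combinations(x: float, s: int) -> float:
    # number of distinct reactant combinations: C(x, s)
    out = 1.0
    for k in range(s):
        out *= (x - k)
    return out / math.factorial(s) if out > 0 else 0.0


def simulate_ssa(
    model: ReactionNetworkModel,
    t0: float,
    t_start: float,
    t_end: float,
    n_points: int,
    config: KernelConfig,
) -> TrajectoryResult:
    """Gillespie direct method over mass-action propensities.

    The state is recorded by zero-order hold: each uniform grid time gets the
    state after the last event at or before it.  The run is fully determined
    by ``config.seed`` (default 0).
    """
    config.check()
    if not (t0 <= t_start <= t_end):
        raise SimexError("BAD_CONFIG", "need t0 <= t_start <= t_end")
    if n_points < 1:
        raise SimexError("BAD_CONFIG", "n_points must be >= 1")
    for s in model.species:
        if s.initial_amount != int(s.initial_amount):
            raise SimexError("BAD_CONFIG", f"species {s.id} initial amount is not an integer")
    warnings: List[str] = []
    index = {s.id: i for i, s in enumerate(model.species)}
    param_values = {p.id: p.value for p in model.parameters}
    n_species = len(model.species)

    # per-reaction: (constant, [(species index, stoich)...]) or a fallback callable
    propensity_spec: List[Tuple[Optional[float], List[Tuple[int, int]], Optional[object]]] = []
    for reaction in model.reactions:
        c = _mass_action_constant(reaction, param_values)
        reactant_idx = [(index[sid], stoich) for sid, stoich in reaction.reactants]
        if c is None:
            warnings.append(
                f"rate of {reaction.id} is not mass-action; propensity falls back to "
                "direct expression evaluation"
            )
            propensity_spec.append((None, reactant_idx, reaction.rate.compile()))
        else:
            propensity_spec.append((c, reactant_idx, None))
    deltas: List[List[Tuple[int, int]]] = []
    for reaction in model.reactions:
        change: Dict[int, int] = {}
        for sid, stoich in reaction.reactants:
            change[index[sid]] = change.get(index[sid], 0) - stoich
        for sid, stoich in reaction.products:
            change[index[sid]] = change.get(index[sid], 0) + stoich
        deltas.append(sorted(change.items()))

    rng = random.Random(config.seed if config.seed is not None else 0)
    x = [float(int(s.initial_amount)) for s in model.species]
    env = dict(param_values)
    species_ids = [s.id for s in model.species]

    def propensities() -> List[float]:
        out = []
        for c, reactant_idx, fallback in propensity_spec:
            if c is not None:
                a = c
                for i, stoich in reactant_idx:
                    a *= _falling_combinations(x[i], stoich)
            else:
                for i, sid in enumerate(species_ids):
                    env[sid] = x[i]
                a = max(0.0, float(fallback(env)))
            out.append(a if a > 0 else 0.0)
        return out

    times = np.linspace(t_start, t_end, n_points + 1)
    values = np.empty((n_species, n_points + 1))
    t = t0
    next_record = 0
    while next_record <= n_points:
        props = propensities()
        total = sum(props)
        if total <= 0.0:
            t_next = float("inf")
        else:
            t_next = t + rng.expovariate(total)
        # hold current state onto every grid point before the next event
        while next_record <= n_points and times[next_record] < t_next:
            values[:, next_record] = x
            next_record += 1
        if next_record > n_points or t_next == float("inf"):
            break
        # fire the chosen reaction
        u = rng.random() * total
        acc = 0.0
        chosen = len(props) - 1
        for j, a in enumerate(props):
            acc += a
            if u <= acc:
                chosen = j
                break
        for i, delta in deltas[chosen]:
            x[i] += delta
        t = t_next
    return TrajectoryResult(times, values, species_ids, warnings)


# ---------------------------------------------------------------------------
# Boolean networks


def simulate_boolean(
    model: BooleanNetworkModel,
    n_steps: int,
    scheme: str = "synchronous",
    seed: Optional[int] = None,
) -> TrajectoryResult:
    """Simulate a Boolean network for ``n_steps`` update steps.

    ``synchronous`` evaluates every update rule against the previous state;
    ``asynchronous`` updates one uniformly chosen node per step (seeded).
    """
    if n_steps < 0:
        raise SimexError("BAD_CONFIG", "n_steps must be >= 0")
    if scheme not in ("synchronous", "asynchronous"):
        raise SimexError("BAD_CONFIG", f"unknown update scheme {scheme!r}")
    node_ids = model.node_ids()
    state = {n.id: n.initial_state for n in model.nodes}
    values = np.empty((len(node_ids), n_steps + 1))
    values[:, 0] = [state[nid] for nid in node_ids]
    rng = random.Random(seed if seed is not None else 0)
    for step in range(1, n_steps + 1):
        if scheme == "synchronous":
            state = {n.id: n.update.evaluate(state) for n in model.nodes}
        else:
            node = model.nodes[rng.randrange(len(model.nodes))]
            state = dict(state)
            state[node.id] = node.update.evaluate(state)
        values[:, step] = [state[nid] for nid in node_ids]
    return TrajectoryResult(np.arange(n_steps + 1, dtype=float), values, node_ids)
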