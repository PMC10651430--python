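"""Mass-action ODE semantics of a PPN and steady-state simulation.

For a transition t with rate constant k, reactant places s (weight w),
promoter places p and inhibitor places i, the reaction rate is

    rate(t) = k * prod_s [s]^w * prod_p [p] * prod_i 1/(1+[i])

and each species' derivative is the stoichiometry-weighted sum of rates:
d[s]/dt = sum_t (product weight - reactant weight) * rate(t).  The
promoter/inhibitor algebra is smooth and bounded and reduces to plain
mass action when a transition has no modifiers; it is recorded on the
:class:`~petridyn.core.KineticLaw` so alternative algebras can be wired
in without touching callers.

Steady states are approximated by integrating with a stiff-capable
adaptive method (LSODA) until the derivative residual max_s |d[s]/dt|
falls below a tolerance, or until a time cap is hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .core import PPN

__all__ = [
    "RateSystem",
    "SteadyState",
    "SimulationError",
    "build_rate_system",
    "simulate_steady_state",
    "simulate_trajectory",
    "steady_state",
    "DEFAULT_TOL",
    "DEFAULT_T_MAX",
]

#: Residual tolerance on max |d[s]/dt| for declaring a steady state.
DEFAULT_TOL = 1e-6
#: Simulated-time cap, in the model's time units.
DEFAULT_T_MAX = 1e5
#: Concentration above which a trajectory is declared divergent.
_BLOWUP_LIMIT = 1e9


class SimulationError(RuntimeError):
    """Integrator failure; carries the partial trajectory."""

    def __init__(self, message: str, times=None, states=None):
        super().__init__(message)
        self.times = times
        self.states = states


@dataclass
class RateSystem:
    """Vectorized ODE right-hand side for a PPN.

    ``species`` fixes the coordinate order of markings.  ``net`` is the
    (n_transitions, n_species) matrix of net stoichiometric changes
    (product weight minus reactant weight); its transpose's left null
    vectors are the conservation laws of the net.
    """

    species: list[str]
    transitions: list[str]
    rate_constants: np.ndarray  # (T,)
    react_exp: np.ndarray  # (T, S) reactant stoichiometric exponents
    pro_exp: np.ndarray  # (T, S) promoter indicators
    inh_exp: np.ndarray  # (T, S) inhibitor indicators
    net: np.ndarray  # (T, S) net change per firing
    index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.index:
            self.index = {s: i for i, s in enumerate(self.species)}

    def rates(self, m: np.ndarray) -> np.ndarray:
        """Reaction rates at marking ``m`` (negative values clipped to 0)."""
        y = np.clip(np.asarray(m, dtype=float), 0.0, None)
        with np.errstate(over="ignore", invalid="ignore"):
            v = self.rate_constants * np.prod(y[None, :] ** self.react_exp, axis=1)
            if self.pro_exp.any():
                v = v * np.prod(y[None, :] ** self.pro_exp, axis=1)
            if self.inh_exp.any():
                v = v * np.prod((1.0 + y[None, :]) ** -self.inh_exp, axis=1)
        return np.nan_to_num(v, nan=0.0, posinf=1e300)

    def derivative(self, m: np.ndarray) -> np.ndarray:
        """d[marking]/dt; zero for species untouched by every transition."""
        return self.net.T @ self.rates(m)

    def marking_vector(self, marking: dict[str, float]) -> np.ndarray:
        return np.array([marking.get(s, 0.0) for s in self.species], dtype=float)

    def marking_dict(self, m: np.ndarray) -> dict[str, float]:
        return {s: float(m[i]) for i, s in enumerate(self.species)}


@dataclass
class SteadyState:
    """Result of a steady-state simulation."""

    marking: dict[str, float]
    converged: bool
    time: float
    residual: float

    def __getitem__(self, place: str) -> float:
        return self.marking[place]


def build_rate_system(ppn: PPN) -> RateSystem:
    """Compile a validated PPN into a :class:`RateSystem`."""
    species = sorted(ppn.places)
    transitions = sorted(ppn.transitions)
    idx = {s: i for i, s in enumerate(species)}
    T, S = len(transitions), len(species)
    k = np.zeros(T)
    react = np.zeros((T, S))
    pro = np.zeros((T, S))
    inh = np.zeros((T, S))
    net = np.zeros((T, S))
    for j, t in enumerate(transitions):
        k[j] = ppn.kinetics[t].rate_constant
        for s, w in ppn.reactants(t):
            react[j, idx[s]] += w
            net[j, idx[s]] -= w
        for s, w in ppn.products(t):
            net[j, idx[s]] += w
        for s in ppn.promoters(t):
            pro[j, idx[s]] = 1
        for s in ppn.inhibitors(t):
            inh[j, idx[s]] = 1
    return RateSystem(species, transitions, k, react, pro, inh, net, idx)


def simulate_steady_state(
    system: RateSystem,
    m0: dict[str, float] | np.ndarray,
    tol: float = DEFAULT_TOL,
    t_max: float = DEFAULT_T_MAX,
) -> SteadyState:
    """Integrate the ODEs until the derivative residual drops below ``tol``.

    Declares convergence when ``max |d[s]/dt| <= tol``; otherwise returns
    the marking reached at ``t_max`` with ``converged=False``.  Negative
    concentrations (solver noise) are clipped to zero in the result.
    """
    if tol <= 0 or t_max <= 0:
        raise ValueError("tol and t_max must be positive")
    y0 = system.marking_vector(m0) if isinstance(m0, dict) else np.asarray(m0, dtype=float)
    if (y0 < 0).any():
        raise ValueError("initial marking must be non-negative")

    res0 = float(np.max(np.abs(system.derivative(y0)))) if len(y0) else 0.0
    if res0 <= tol:
        return SteadyState(system.marking_dict(np.clip(y0, 0, None)), True, 0.0, res0)

    def rhs(_t, y):
        return system.derivative(y)

    def settle(_t, y):
        return float(np.max(np.abs(system.derivative(y)))) - tol

    settle.terminal = True
    settle.direction = -1

    def blow_up(_t, y):  # divergence guard: stop runaway trajectories
        return float(np.max(y)) - _BLOWUP_LIMIT

    blow_up.terminal = True
    blow_up.direction = 1

    sol = solve_ivp(
        rhs, (0.0, t_max), y0, method="LSODA", events=(settle, blow_up), rtol=1e-8, atol=1e-10
    )
    if not sol.success:
        raise SimulationError(f"integrator failure: {sol.message}", sol.t, sol.y)
    y_end = np.clip(sol.y[:, -1], 0.0, None)
    t_end = float(sol.t[-1])
    residual = float(np.max(np.abs(system.derivative(y_end))))
    settled = sol.status == 1 and len(sol.t_events[0]) > 0
    converged = settled or residual <= tol
    return SteadyState(system.marking_dict(y_end), converged, t_end, residual)


def simulate_trajectory(
    system: RateSystem,
    m0: dict[str, float] | np.ndarray,
    t_points: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate and sample the trajectory at ``t_points``.

    Returns ``(times, states)`` with ``states`` of shape
    (n_species, n_times) in the system's species order.
    """
    y0 = system.marking_vector(m0) if isinstance(m0, dict) else np.asarray(m0, dtype=float)
    t_points = np.asarray(t_points, dtype=float)
    sol = solve_ivp(
        lambda _t, y: system.derivative(y),
        (float(t_points[0]), float(t_points[-1])),
        y0,
        method="LSODA",
        t_eval=t_points,
        rtol=1e-8,
        atol=1e-10,
    )
    if not sol.success:
        raise SimulationError(f"integrator failure: {sol.message}", sol.t, sol.y)
    return sol.t, np.clip(sol.y, 0.0, None)


def steady_state(
    ppn: PPN,
    overrides: dict[str, float] | None = None,
    tol: float = DEFAULT_TOL,
    t_max: float = DEFAULT_T_MAX,
) -> SteadyState:
    """Convenience wrapper: compile ``ppn`` and simulate from its initial
    marking, optionally overriding selected species' initial values."""
    system = build_rate_system(ppn)
    m0 = dict(ppn.initial_marking)
    if overrides:
        m0.update(overrides)
    return simulate_steady_state(system, m0, tol=tol, t_max=t_max)
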