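"""Dynamical properties of (input, output) species pairs.

Three properties are assessed by repeated steady-state simulation:

alpha-robustness
    Sweep the input species' initial concentration across a relative
    interval of width epsilon around its nominal value, record the output
    species' steady-state concentration, and compute the output variation
    range alpha = max - min.  With abar the range relative to the output
    scale, robustness is ``1 - min(1, abar / epsilon)``: 1 means the
    output never moved, 0 means it moved at least as much (relatively) as
    the input was perturbed.

Morris sensitivity
    Global screening via elementary effects (EEs).  An EE is the change
    in the output's steady state induced by perturbing one input factor
    by Delta, sampled over the whole input domain with a radial design
    built on a Sobol sequence.  mu* (mean |EE|) measures overall
    influence, sigma (spread of the EEs) measures interaction with other
    factors; the pair is sensitive when either exceeds its threshold.

Monotonic influence
    The input is monotonically influential when every EE in the pool is
    strictly positive — perturbations always push the output the same
    way.

The EE here is the difference quotient (f(x+De_i)-f(x))/D; the undivided
difference f(x+De_i)-f(x) is available via ``undivided=True`` (the two
coincide when D=1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.stats import qmc

from .core import PPN
from .dynamics import DEFAULT_T_MAX, DEFAULT_TOL, RateSystem, build_rate_system, simulate_steady_state

__all__ = [
    "SimSettings",
    "RobustnessConfig",
    "RobustnessResult",
    "MorrisConfig",
    "SensitivityResult",
    "PropertyLabel",
    "RadialBlock",
    "elementary_effect",
    "radial_sobol_plan",
    "assess_robustness",
    "assess_sensitivity",
    "assess_monotonicity",
    "assess_property",
]


@dataclass(frozen=True)
class SimSettings:
    """Steady-state simulation settings shared by all assessments."""

    tol: float = DEFAULT_TOL
    t_max: float = DEFAULT_T_MAX


@dataclass(frozen=True)
class RobustnessConfig:
    """Settings for the alpha-robustness sweep.

    ``epsilon`` is the relative width of the input sweep interval
    [nominal*(1-eps/2), nominal*(1+eps/2)]; when the nominal input is 0
    the absolute interval [0, eps] is used.  ``n_grid`` initial
    concentrations are sampled uniformly across the interval.
    ``output_scale`` normalizes the output range; ``None`` selects the
    nominal (unperturbed) steady-state output, falling back to the
    maximum observed output so that the relative range lands in [0, 1].
    ``threshold`` binarizes the continuous robustness value.
    """

    epsilon: float = 0.2
    n_grid: int = 21
    output_scale: float | None = None
    threshold: float = 0.5

    def __post_init__(self) -> None:
        if not 0 < self.epsilon <= 1:
            raise ValueError("epsilon must lie in (0, 1]")
        if self.n_grid < 3:
            raise ValueError("n_grid must be >= 3")


@dataclass
class RobustnessResult:
    alpha: float  # absolute output variation range (max - min)
    alpha_rel: float  # relative output range, in [0, 1]
    center: float  # midpoint of the output interval
    value: float  # 1 - min(1, alpha_rel / epsilon)
    binary: bool
    reliable: bool = True
    inputs: np.ndarray | None = None
    outputs: np.ndarray | None = None


@dataclass(frozen=True)
class MorrisConfig:
    """Settings for the Morris elementary-effects screening.

    ``r`` radial blocks; ``delta_frac`` is the perturbation Delta as a
    fraction of each factor's range; per-factor ranges are
    [lower_frac*nominal, upper_frac*nominal] (or [0, 1] for species with
    nominal 0).  ``mu_threshold``/``sigma_threshold`` binarize
    sensitivity.  With ``zero_policy='break'`` (strict default) an EE
    with |EE| <= zero_tol breaks monotonicity; ``'ignore'`` drops it from
    the monotonicity check instead.
    """

    r: int = 16
    delta_frac: float = 0.1
    mu_threshold: float = 0.1
    sigma_threshold: float = 0.1
    seed: int = 0
    lower_frac: float = 0.5
    upper_frac: float = 1.5
    undivided: bool = False
    zero_tol: float = 0.0
    zero_policy: str = "break"

    def __post_init__(self) -> None:
        if self.r < 2:
            raise ValueError("r must be >= 2")
        if not 0 < self.delta_frac < 1:
            raise ValueError("delta_frac must lie in (0, 1)")
        if self.mu_threshold < 0 or self.sigma_threshold < 0:
            raise ValueError("thresholds must be >= 0")
        if self.zero_policy not in ("break", "ignore"):
            raise ValueError("zero_policy must be 'break' or 'ignore'")


@dataclass
class SensitivityResult:
    ee_list: list[float]
    mu_star: float
    sigma: float
    sensitive: bool
    monotone: bool
    reliable: bool = True
    n_dropped: int = 0


@dataclass(frozen=True)
class PropertyLabel:
    """(property name, raw continuous value where applicable, binary label)."""

    property: str
    raw: float | None
    binary: bool


# ---------------------------------------------------------------------------
# Elementary effects and the radial Sobol design


def elementary_effect(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    i: int,
    delta: float,
    undivided: bool = False,
) -> float:
    """EE of factor ``i`` at point ``x``: (f(x + delta*e_i) - f(x)) / delta.

    ``delta`` may be negative (the quotient keeps the slope's sign).
    ``undivided=True`` returns the raw difference instead; delta = 1
    makes the two forms coincide.
    """
    if delta == 0:
        raise ValueError("delta must be nonzero")
    x = np.asarray(x, dtype=float)
    xp = x.copy()
    xp[i] += delta
    diff = f(xp) - f(x)
    return float(diff) if undivided else float(diff / delta)


@dataclass(frozen=True)
class RadialBlock:
    """One radial block: a Sobol base point and k one-coordinate companions."""

    base: np.ndarray  # (k,)
    points: np.ndarray  # (k, k); row i differs from base in coordinate i only
    deltas: np.ndarray  # (k,) signed unit-cube perturbations


def radial_sobol_plan(k: int, r: int, seed: int, delta: float = 0.1) -> list[RadialBlock]:
    """Radial sampling plan: ``r`` Sobol base points, each with ``k``
    companions differing in exactly one coordinate by +/- ``delta``.

    The sign is flipped (reflection) whenever a step would leave the unit
    hypercube, so all points stay in [0, 1]^k.  Deterministic given
    ``seed``.  Total simulation budget of the plan: r * (k + 1) points.
    """
    if k < 1 or r < 1:
        raise ValueError("k and r must be >= 1")
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    sampler = qmc.Sobol(d=k, scramble=True, seed=seed)
    with warnings.catch_warnings():
        # radial designs legitimately use arbitrary r, not powers of two
        warnings.filterwarnings("ignore", message=".*power of 2.*")
        bases = sampler.random(r)
    blocks = []
    for b in bases:
        deltas = np.where(b + delta <= 1.0, delta, -delta)
        pts = np.tile(b, (k, 1))
        pts[np.arange(k), np.arange(k)] += deltas
        blocks.append(RadialBlock(base=b.copy(), points=pts, deltas=deltas))
    return blocks


# ---------------------------------------------------------------------------
# Property assessments


def _check_pair(ppn: PPN, input: str, output: str) -> None:
    if input not in ppn.places:
        raise KeyError(f"input {input!r} is not a place of the PPN")
    if output not in ppn.places:
        raise KeyError(f"output {output!r} is not a place of the PPN")


def _ss_output(system: RateSystem, m0: np.ndarray, output_idx: int, sim: SimSettings):
    ss = simulate_steady_state(system, m0, tol=sim.tol, t_max=sim.t_max)
    return ss.marking[system.species[output_idx]], ss.converged


def assess_robustness(
    ppn: PPN,
    input: str,
    output: str,
    cfg: RobustnessConfig | None = None,
    sim: SimSettings | None = None,
) -> RobustnessResult:
    """alpha-robustness of ``output``'s steady state to perturbations of
    ``input``'s initial concentration.

    All species other than the input start at their nominal initial
    marking for every simulation in the sweep.
    """
    cfg = cfg or RobustnessConfig()
    sim = sim or SimSettings()
    _check_pair(ppn, input, output)
    system = build_rate_system(ppn)
    i_in = system.index[input]
    i_out = system.index[output]
    m0 = system.marking_vector(ppn.initial_marking)
    nominal = m0[i_in]
    if nominal > 0:
        lo, hi = nominal * (1 - cfg.epsilon / 2), nominal * (1 + cfg.epsilon / 2)
    else:
        lo, hi = 0.0, cfg.epsilon
    sweep = np.linspace(lo, hi, cfg.n_grid)

    outputs = np.empty(cfg.n_grid)
    reliable = True
    for j, val in enumerate(sweep):
        m = m0.copy()
        m[i_in] = val
        out, converged = _ss_output(system, m, i_out, sim)
        outputs[j] = out
        reliable &= converged

    alpha = float(outputs.max() - outputs.min())
    center = float((outputs.max() + outputs.min()) / 2)

    scale = cfg.output_scale
    if scale is None:
        nominal_out, converged = _ss_output(system, m0, i_out, sim)
        reliable &= converged
        scale = nominal_out
    if scale <= 0 or alpha > scale:
        scale = float(outputs.max())  # fallback keeps alpha_rel in [0, 1]
    if scale <= 0:
        if alpha == 0:
            alpha_rel = 0.0
        else:
            warnings.warn("all-zero output scale with nonzero range; relative range saturated at 1")
            alpha_rel = 1.0
    else:
        alpha_rel = alpha / scale
    value = 1.0 - min(1.0, alpha_rel / cfg.epsilon)
    return RobustnessResult(
        alpha=alpha,
        alpha_rel=alpha_rel,
        center=center,
        value=value,
        binary=value >= cfg.threshold,
        reliable=reliable,
        inputs=sweep,
        outputs=outputs,
    )


def _factor_ranges(system: RateSystem, m0: np.ndarray, varied: Sequence[int], cfg: MorrisConfig) -> np.ndarray:
    """(k, 2) array of [lo, hi] marking ranges for the varied species."""
    ranges = np.empty((len(varied), 2))
    for j, idx in enumerate(varied):
        nom = m0[idx]
        if nom > 0:
            ranges[j] = (cfg.lower_frac * nom, cfg.upper_frac * nom)
        else:
            ranges[j] = (0.0, 1.0)
    return ranges


def assess_sensitivity(
    ppn: PPN,
    input: str,
    output: str,
    cfg: MorrisConfig | None = None,
    sim: SimSettings | None = None,
) -> SensitivityResult:
    """Morris screening of ``output``'s steady state w.r.t. ``input``.

    The varied factors are the initial concentrations of every place
    except the output; each radial block contributes the EE of the
    designated input factor.  Non-converged simulations are dropped from
    the EE pool; the result is flagged unreliable when more than half of
    the blocks are lost.
    """
    cfg = cfg or MorrisConfig()
    sim = sim or SimSettings()
    _check_pair(ppn, input, output)
    system = build_rate_system(ppn)
    varied = [i for i, s in enumerate(system.species) if s != output]
    if system.index[input] not in varied:
        raise ValueError("input must differ from output")
    k = len(varied)
    pos = varied.index(system.index[input])
    m0 = system.marking_vector(ppn.initial_marking)
    ranges = _factor_ranges(system, m0, varied, cfg)
    span = ranges[:, 1] - ranges[:, 0]
    plan = radial_sobol_plan(k, cfg.r, cfg.seed, delta=cfg.delta_frac)

    def to_marking(u: np.ndarray) -> np.ndarray:
        m = m0.copy()
        m[varied] = ranges[:, 0] + u * span
        return m

    i_out = system.index[output]
    ees: list[float] = []
    dropped = 0
    for block in plan:
        f_base, ok_base = _ss_output(system, to_marking(block.base), i_out, sim)
        f_pert, ok_pert = _ss_output(system, to_marking(block.points[pos]), i_out, sim)
        if not (ok_base and ok_pert):
            dropped += 1
            continue
        delta_x = block.deltas[pos] * span[pos]  # perturbation in concentration units
        diff = f_pert - f_base
        ees.append(float(diff) if cfg.undivided else float(diff / delta_x))

    if not ees:
        return SensitivityResult([], 0.0, 0.0, False, False, reliable=False, n_dropped=dropped)
    arr = np.array(ees)
    mu_star = float(np.mean(np.abs(arr)))
    sigma = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    sensitive = mu_star > cfg.mu_threshold or sigma > cfg.sigma_threshold
    monotone = _monotone(arr, cfg)
    reliable = dropped <= cfg.r / 2
    return SensitivityResult(ees, mu_star, sigma, sensitive, monotone, reliable, dropped)


def _monotone(ees: np.ndarray, cfg: MorrisConfig) -> bool:
    if cfg.zero_policy == "ignore":
        ees = ees[np.abs(ees) > cfg.zero_tol]
        if len(ees) == 0:
            return False
        return bool((ees > 0).all())
    return bool((ees > cfg.zero_tol).all())


def assess_monotonicity(sens: SensitivityResult, cfg: MorrisConfig | None = None) -> bool:
    """True iff every EE in the pool is strictly positive.

    Near-zero EEs are handled per the config's zero policy (the strict
    default treats them as breaking monotonicity).
    """
    cfg = cfg or MorrisConfig()
    if not sens.ee_list:
        raise ValueError("empty elementary-effect pool: monotonicity undefined")
    return _monotone(np.array(sens.ee_list), cfg)


def assess_property(
    ppn: PPN,
    input: str,
    output: str,
    property: str,
    robustness_cfg: RobustnessConfig | None = None,
    morris_cfg: MorrisConfig | None = None,
    sim: SimSettings | None = None,
) -> PropertyLabel:
    """Assess one named property for a (PPN, input, output) triple."""
    if property == "robustness":
        res = assess_robustness(ppn, input, output, robustness_cfg, sim)
        return PropertyLabel("robustness", res.value, res.binary)
    if property == "sensitivity":
        res = assess_sensitivity(ppn, input, output, morris_cfg, sim)
        return PropertyLabel("sensitivity", res.mu_star, res.sensitive)
    if property == "monotonicity":
        res = assess_sensitivity(ppn, input, output, morris_cfg, sim)
        if not res.ee_list:
            raise ValueError("empty elementary-effect pool: monotonicity undefined")
        return PropertyLabel("monotonicity", None, res.monotone)
    raise ValueError(f"unknown property {property!r}")
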