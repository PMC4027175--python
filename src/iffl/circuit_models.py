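"""ODE right-hand sides and the simulation driver for all adapter-circuit model variants.

Model variants
--------------
``simple``
    Three species -- repressor x = [iMG], output y = [rMG], complex
    z = [rMG.iMG] -- with first-order enzyme kinetics:

    .. math::

        \\dot x = \\alpha_1 u - \\beta_1 x - k x y + \\gamma_1 z,\\quad
        \\dot y = \\alpha_2 u - k x y,\\quad
        \\dot z = k x y - \\gamma_1 z.

``mm``
    The same network with Michaelis--Menten saturation factors
    ``f(u) = 1/(1 + u/K_M)`` on transcription and
    ``g(x, z) = 1/(1 + x/K_Mx + z/K_Mz)`` on RNase-R degradation.

``nondim``
    The dimensionless form in scaled variables (all 1 at steady state,
    time in units of 1/beta1):

    .. math::

        \\dot x = u - x - p_1 (x y - z),\\quad
        \\dot y = p_2 (u - x y),\\quad
        \\dot z = p_3 (x y - z).

``fcd_limit``
    The fold-change-detection limit (small p1, large p2):
    ``dX/dt = F - X`` with output ``y = F/X``, where F is the input fold
    relative to its baseline.  Dynamics depend only on input folds.

``detailed``
    Five species with explicit template--activator binding at rate
    ``k_plus``: activated templates [TiMG.A], [TrMG.A] produce x and y;
    free activator follows from the conservation relation
    ``[A] = [A_tot] - [TiMG.A] - [TrMG.A]``.

Inputs are piecewise constant; the integrator is stopped and restarted at
every addition time so each segment sees a smooth right-hand side.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from scipy.integrate import solve_ivp

from .params import CircuitConfig, DerivedRates, NondimParams, RateParams, derived_rates
from .schedule import InputSchedule, input_u
from .trace import SimOptions, Trace

MODEL_KINDS = ("simple", "mm", "nondim", "detailed", "fcd_limit")

_NEG_TOL = 1e-6  # nM; states below this are an integration failure


class SimulationError(RuntimeError):
    """Solver failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:g})")
        self.last_time = last_time


def burst_rate(t: float, rates: RateParams) -> float:
    """Effective rMG transcription rate constant during the burst phase.

    ``kp2_burst(t) = kp2 * (1 + B * exp(-t/tau_b))``: the first turnovers
    after enzyme addition are faster than the steady transcription rate.
    Monotone nonincreasing for B > 0 and -> kp2 as t -> inf.
    """
    if rates.B == 0:
        return rates.kp2
    return rates.kp2 * (1.0 + rates.B * math.exp(-t / rates.tau_b))


def _burst_factor(t: float, rates: Optional[RateParams]) -> float:
    if rates is None or rates.B == 0:
        return 1.0
    return 1.0 + rates.B * math.exp(-t / rates.tau_b)


def rhs_simple(state: Sequence[float], u: float, dr: DerivedRates, k: float,
               alpha2_factor: float = 1.0) -> Tuple[float, float, float]:
    """First-order-kinetics IFFL right-hand side (x, y, z derivatives).

    ``alpha2_factor`` multiplies the output production term (burst phase).
    """
    x, y, z = state
    kxy = k * x * y
    dx = dr.alpha1 * u - dr.beta1_eff * x - kxy + dr.gamma1_eff * z
    dy = dr.alpha2 * alpha2_factor * u - kxy
    dz = kxy - dr.gamma1_eff * z
    return dx, dy, dz


def mm_saturation(u: float, x: float, z: float,
                  rates: RateParams) -> Tuple[float, float]:
    """RNAP and RNase-R saturation factors f(u), g(x, z)."""
    f = 1.0 / (1.0 + u / rates.K_M)
    g = 1.0 / (1.0 + x / rates.K_M_R_x + z / rates.K_M_R_z)
    return f, g


def rhs_mm(state: Sequence[float], u: float, dr: DerivedRates,
           rates: RateParams, alpha2_factor: float = 1.0) -> Tuple[float, float, float]:
    """Michaelis--Menten variant: saturable transcription and degradation."""
    x, y, z = state
    f, g = mm_saturation(u, x, z, rates)
    kxy = rates.k * x * y
    dx = dr.alpha1 * u * f - dr.beta1_eff * x * g - kxy + dr.gamma1_eff * z * g
    dy = dr.alpha2 * alpha2_factor * u * f - kxy
    dz = kxy - dr.gamma1_eff * z * g
    return dx, dy, dz


def rhs_nondim(state: Sequence[float], u: float, p1: float, p2: float,
               p3: float) -> Tuple[float, float, float]:
    """Dimensionless IFFL right-hand side (scaled x, y, z derivatives)."""
    x, y, z = state
    xy_z = x * y - z
    return (u - x - p1 * xy_z, p2 * (u - x * y), p3 * xy_z)


def rhs_detailed(state: Sequence[float], u: float, rates: RateParams,
                 config: CircuitConfig, t: float = 0.0,
                 conservation_tol: float = 1e-6) -> Tuple[float, ...]:
    """Mass-action model with explicit template activation.

    State is ``(TiA, TrA, x, y, z)``; ``u`` is the running [A_tot].  Free
    activator and free templates follow from conservation.  Degradation of
    rMG within the complex (gamma1) recycles the iMG strand into x;
    degradation of iMG within the complex (gamma2) releases rMG back into y.
    """
    TiA, TrA, x, y, z = state
    a_free = u - TiA - TrA
    if a_free < -conservation_tol * max(1.0, u):
        raise SimulationError(
            f"activator conservation violated: bound {TiA + TrA:g} > total {u:g}", t)
    a_free = max(a_free, 0.0)
    ti_free = max(config.TiMG_tot - TiA, 0.0)
    tr_free = max(config.TrMG_tot - TrA, 0.0)

    rnap_scale = config.rnap / config.rnap_ref if config.rnap_ref > 0 else 0.0
    rnase_scale = (config.rnase_r / config.rnase_r_ref
                   if config.rnase_r_ref > 0 else 0.0)
    beta1 = rates.beta1 * rnase_scale
    gamma1 = rates.gamma1 * rnase_scale
    gamma2 = rates.gamma2 * rnase_scale
    kp2_eff = burst_rate(t, rates) * rnap_scale
    kp1_eff = rates.kp1 * rnap_scale

    d_TiA = rates.k_plus * a_free * ti_free
    d_TrA = rates.k_plus * a_free * tr_free
    kxy = rates.k * x * y
    dx = kp1_eff * TiA - beta1 * x - kxy + gamma1 * z
    dy = kp2_eff * TrA - kxy - rates.beta2 * y + gamma2 * z
    dz = kxy - (gamma1 + gamma2) * z
    return d_TiA, d_TrA, dx, dy, dz


def _segments(schedule: Optional[InputSchedule], t_end: float):
    """Breakpoints [0, event times..., t_end] with the constant u of each segment."""
    times = [0.0]
    if schedule is not None:
        for e in schedule.events:
            if e.time > t_end:
                break
            if e.time > times[-1]:
                times.append(e.time)
    times.append(t_end)
    out = []
    for a, b in zip(times[:-1], times[1:]):
        if b <= a:
            continue
        u = input_u(schedule, a) if schedule is not None else 0.0
        out.append((a, b, u))
    return out


def _grid(a: float, b: float, dt: float) -> np.ndarray:
    n = max(int(math.ceil((b - a) / dt)), 1)
    return np.linspace(a, b, n + 1)


def simulate(
    model_kind: str,
    rates: Optional[RateParams] = None,
    config: Optional[CircuitConfig] = None,
    schedule: Optional[InputSchedule] = None,
    options: Optional[SimOptions] = None,
    initial_state: Optional[Sequence[float]] = None,
    nondim: Optional[Union[NondimParams, Tuple[float, float, float]]] = None,
) -> Trace:
    """Integrate one model variant under a piecewise-constant input protocol.

    The integration is restarted at every addition time; state is continuous
    across events (only the input jumps), except that in the detailed model
    an inhibitor addition that out-titrates the bound activator strips
    template-bound A proportionally.

    Returns a :class:`Trace` sampled on the requested output grid plus the
    exact event times; series always include the input ``u``.
    """
    if model_kind not in MODEL_KINDS:
        raise ValueError(f"unknown model kind {model_kind!r}; expected one of {MODEL_KINDS}")
    options = options or SimOptions()
    if schedule is not None and any(e.time < 0 for e in schedule.events):
        raise ValueError("schedule events must not precede t=0")

    segs = _segments(schedule, options.t_end)

    if model_kind in ("simple", "mm"):
        if rates is None or config is None:
            raise ValueError(f"{model_kind} model needs rates and config")
        dr = derived_rates(config, rates)
        y0 = np.zeros(3) if initial_state is None else np.asarray(initial_state, float)
        names = ("x", "y", "z")

        def make_rhs(u):
            if model_kind == "simple":
                return lambda t, s: rhs_simple(s, u, dr, rates.k, _burst_factor(t, rates))
            return lambda t, s: rhs_mm(s, u, dr, rates, _burst_factor(t, rates))

    elif model_kind == "nondim":
        if nondim is None:
            raise ValueError("nondim model needs p1, p2, p3")
        if isinstance(nondim, NondimParams):
            p1, p2, p3 = nondim.p1, nondim.p2, nondim.p3
        else:
            p1, p2, p3 = nondim
        if min(p1, p2, p3) <= 0:
            raise ValueError("p1, p2, p3 must be positive")
        y0 = np.ones(3) if initial_state is None else np.asarray(initial_state, float)
        names = ("x", "y", "z")

        def make_rhs(u):
            return lambda t, s: rhs_nondim(s, u, p1, p2, p3)

    elif model_kind == "detailed":
        if rates is None or config is None:
            raise ValueError("detailed model needs rates and config")
        y0 = np.zeros(5) if initial_state is None else np.asarray(initial_state, float)
        names = ("TiA", "TrA", "x", "y", "z")

        def make_rhs(u):
            return lambda t, s: rhs_detailed(s, u, rates, config, t)

    else:  # fcd_limit
        if not segs or segs[0][2] <= 0:
            raise ValueError("fcd_limit model requires a positive input from t=0")
        u_base = segs[0][2]
        y0 = (np.array([1.0]) if initial_state is None
              else np.asarray(initial_state, float))
        names = ("X",)

        def make_rhs(u):
            F = u / u_base
            if F <= 0:
                raise ValueError("fcd_limit input must stay positive")
            return lambda t, s: (F - s[0],)

    ts = [np.array([0.0])]
    ys = [y0.reshape(-1, 1)]
    us = [np.array([segs[0][2] if segs else 0.0])]
    state = np.array(y0, dtype=float)

    for a, b, u in segs:
        if model_kind == "detailed":
            bound = state[0] + state[1]
            if bound > u > 0:
                state[:2] *= u / bound  # inhibitor strips template-bound A
            elif bound > 0 and u == 0:
                state[:2] = 0.0
        t_eval = _grid(a, b, options.grid_dt)
        sol = solve_ivp(make_rhs(u), (a, b), state, method=options.method,
                        t_eval=t_eval, rtol=options.rtol, atol=options.atol,
                        max_step=options.max_step)
        if not sol.success:
            raise SimulationError(f"solver failed: {sol.message}",
                                  sol.t[-1] if len(sol.t) else a)
        state = sol.y[:, -1].copy()
        ts.append(sol.t[1:])
        ys.append(sol.y[:, 1:])
        us.append(np.full(len(sol.t) - 1, u))

    t = np.concatenate(ts)
    y = np.concatenate(ys, axis=1)
    # the reported input is right-continuous: a sample at an event time sees
    # the post-addition level (additions are instantaneous)
    if schedule is not None:
        u_arr = np.array([input_u(schedule, tt) for tt in t])
    else:
        u_arr = np.concatenate(us)

    if y.min() < -_NEG_TOL:
        raise SimulationError(
            f"negative concentration {y.min():.3g} beyond tolerance",
            t[int(np.argmin(y.min(axis=0)))])
    y = np.clip(y, 0.0, None)

    series = {name: y[i] for i, name in enumerate(names)}
    series["u"] = u_arr
    if model_kind == "fcd_limit":
        F = u_arr / segs[0][2]
        with np.errstate(divide="ignore", invalid="ignore"):
            series["y"] = np.where(series["X"] > 0, F / series["X"], np.nan)
        series["F"] = F

    meta = {
        "model": model_kind,
        "t_unit": "tau" if model_kind in ("nondim", "fcd_limit") else "min",
        "conc_unit": ("dimensionless" if model_kind in ("nondim", "fcd_limit")
                      else "nM"),
        "schedule": [(e.time, e.species, e.amount) for e in schedule.events]
        if schedule is not None else [],
        "options": {"rtol": options.rtol, "atol": options.atol,
                    "grid_dt": options.grid_dt, "t_end": options.t_end},
    }
    return Trace(t, series, meta)
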