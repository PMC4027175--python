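"""Parameter estimation from fluorescence traces.

The workflow mirrors how the circuit is characterized at the bench:

1. :func:`correct_background` -- fit and subtract the exponentially
   bleaching free-dye background from a pre-reaction blank window.
2. :func:`calibrate` -- convert fluorescence to rMG concentration with a
   linear standard curve through the origin.
3. Elementary-reaction fits: :func:`fit_transcription` (production rate and
   burst phase), :func:`fit_binding` (rMG/iMG hybridization rate), and
   :func:`fit_degradation` (RNase-R degradation of the complex with iMG
   recycling).  These supply the "default" parameter set.
4. :func:`refine_global` -- bounded nonlinear least squares of the full
   three-species circuit model against a set of traces recorded under
   different enzyme/template conditions, sharing one parameter vector.

Production parameters get narrow bounds around their elementary estimates;
the binding and degradation constants are allowed a decade in either
direction, since crude extracts (abortive transcripts, nonspecific
binding) systematically shift them from purified-component values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import lmfit
import numpy as np
from scipy.optimize import least_squares

from .circuit_models import simulate
from .params import CircuitConfig, RateParams, derived_rates
from .schedule import InputSchedule
from .synthetic_data import binding_decay, degradation_mini_model
from .trace import SimOptions, Trace

GLOBAL_PARAM_NAMES = ("kp1", "kp2", "B", "tau_b", "k", "beta1", "gamma1")


@dataclass
class FitResult:
    """Estimates with uncertainties and fit diagnostics."""

    estimates: Dict[str, float]
    residual_ss: float
    converged: bool
    stderr: Dict[str, Optional[float]] = field(default_factory=dict)
    bounds_used: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    meta: Dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.estimates[name]

    def at_bound(self, rel_tol: float = 1e-3) -> List[str]:
        """Names of parameters pinned at a bound of the search box."""
        pinned = []
        for name, (lo, hi) in self.bounds_used.items():
            v = self.estimates.get(name)
            if v is None:
                continue
            span = hi - lo
            if span > 0 and (abs(v - lo) < rel_tol * span
                             or abs(v - hi) < rel_tol * span):
                pinned.append(name)
        return pinned


def correct_background(raw: Trace,
                       blank_window: Optional[Tuple[float, float]] = None,
                       blank: Optional[Trace] = None,
                       signal: str = "fluor") -> Tuple[Trace, FitResult]:
    """Fit the bleaching background and subtract it from the trace.

    The ``amp*exp(-rate*t)`` background is fitted either on a
    ``blank_window = (t0, t1)`` of ``raw`` covering samples recorded before
    the reaction produces signal, or -- more precisely -- on a dedicated
    ``blank`` measurement (dye and buffer without templates) spanning the
    full experiment, the way bleaching is characterized separately at the
    bench.  The fitted curve is extrapolated and subtracted from the whole
    trace.  A fitted rate <= 0 (non-decaying background) is flagged as a
    warning, not an error.
    """
    if blank is not None:
        source = blank
        if blank_window is None:
            blank_window = (float(blank.t[0]), float(blank.t[-1]))
    elif blank_window is not None:
        source = raw
    else:
        raise ValueError("need a blank_window or a dedicated blank trace")
    t0, t1 = blank_window
    mask = (source.t >= t0) & (source.t <= t1)
    if mask.sum() < 3:
        raise ValueError("blank window must contain at least 3 samples")
    t_w, y_w = source.t[mask], source[signal][mask]

    model = lmfit.Model(lambda t, amp, rate: amp * np.exp(-rate * t))
    amp0 = max(float(y_w[0]), 1e-12)
    # crude initial rate from the endpoints of the window
    if y_w[-1] > 0 and y_w[0] > 0 and t_w[-1] > t_w[0]:
        rate0 = max(math.log(max(y_w[0], 1e-12) / max(y_w[-1], 1e-12))
                    / (t_w[-1] - t_w[0]), 1e-6)
    else:
        rate0 = 1e-3
    out = model.fit(y_w, t=t_w, amp=amp0, rate=rate0)
    amp, rate = out.params["amp"].value, out.params["rate"].value

    warnings = []
    if rate <= 0:
        warnings.append("fitted background rate <= 0 (non-decaying)")
    corrected = raw[signal] - amp * np.exp(-rate * raw.t)
    fit = FitResult(
        estimates={"bleach_amp": amp, "bleach_rate": rate},
        residual_ss=float(np.sum(out.residual**2)),
        converged=bool(out.success),
        stderr={"bleach_amp": out.params["amp"].stderr,
                "bleach_rate": out.params["rate"].stderr},
        warnings=warnings,
        meta={"blank_window": blank_window,
              "dedicated_blank": blank is not None},
    )
    out_trace = raw.with_series(**{signal: corrected})
    out_trace.meta = dict(raw.meta, background_corrected=True,
                          bleach_amp=amp, bleach_rate=rate)
    return out_trace, fit


def calibrate(trace: Trace, standards: Sequence[Tuple[float, float]],
              signal: str = "fluor", out_name: str = "rMG") -> Tuple[Trace, float]:
    """Convert fluorescence to concentration with a through-origin line.

    ``standards`` is a list of (concentration nM, fluorescence a.u.) pairs
    from known amounts of purified aptamer.  Returns the trace in nM and
    the fitted slope (a.u./nM).
    """
    if len(standards) < 1:
        raise ValueError("need at least one calibration standard")
    conc = np.array([s[0] for s in standards], float)
    au = np.array([s[1] for s in standards], float)
    if (conc <= 0).any():
        raise ValueError("standard concentrations must be positive")
    slope = float(np.sum(au * conc) / np.sum(conc**2))
    if slope <= 0:
        raise ValueError(f"non-positive calibration slope {slope:g}")
    out = trace.with_series(**{out_name: trace[signal] / slope})
    del out.series[signal]
    out.meta = dict(trace.meta, units="nM", calibration_slope=slope)
    return out, slope


def fit_binding(trace: Trace, c0: float, signal: str = "rMG") -> FitResult:
    """Second-order hybridization fit: [rMG](t) = 1/(k t + 1/c0).

    The reciprocal intercept is fixed by the known initial concentration,
    matching the form used to report the hybridization rate; only k is
    free.  A trace that rises with time beyond 3 sigma of its scatter is
    flagged (binding can only consume free rMG).
    """
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    model = lmfit.Model(lambda t, k: binding_decay(t, k, c0))
    out = model.fit(trace[signal], t=trace.t,
                    k=lmfit.Parameter("k", value=1e-3, min=0))
    warnings = []
    dy = np.diff(trace[signal])
    if len(dy) and dy.mean() > 3 * dy.std(ddof=1) / math.sqrt(len(dy)):
        warnings.append("trace increases with time beyond noise")
    return FitResult(
        estimates={"k": out.params["k"].value, "intercept": 1.0 / c0},
        residual_ss=float(np.sum(out.residual**2)),
        converged=bool(out.success),
        stderr={"k": out.params["k"].stderr},
        warnings=warnings,
        meta={"c0_nM": c0},
    )


def _production_curve(t: np.ndarray, rate: float, B: float,
                      tau_b: float) -> np.ndarray:
    """Accumulated product of dy/dt = rate*(1 + B exp(-t/tau_b))."""
    if B == 0:
        return rate * t
    return rate * (t + B * tau_b * (1.0 - np.exp(-t / tau_b)))


def fit_transcription(traces: Sequence[Trace], config: CircuitConfig,
                      a_concs: Optional[Sequence[float]] = None,
                      fit_burst: bool = True,
                      signal: str = "rMG") -> FitResult:
    """Joint burst-phase fit of production-only traces at several activator levels.

    A single transcription rate constant ``kp2`` (and shared burst
    parameters B, tau_b) is fitted across all traces, enforcing the
    linearity of the production rate in the activator concentration.
    """
    if len(traces) < 2:
        raise ValueError("need traces at >= 2 activator levels")
    if a_concs is None:
        a_concs = [tr.meta["A_tot_nM"] for tr in traces]
    if any(len(tr.t) < 3 for tr in traces):
        raise ValueError("degenerate design: traces need >= 3 time points")
    dr_unit = derived_rates(config, RateParams(kp1=0, kp2=1.0, k=1e-3,
                                               beta1=1e-3, gamma1=1e-3))
    alpha2_per_kp2 = dr_unit.alpha2  # template-fraction + enzyme weighting

    slope0 = np.median([
        (tr[signal][-1] - tr[signal][len(tr.t) // 2])
        / (tr.t[-1] - tr.t[len(tr.t) // 2]) / (alpha2_per_kp2 * u)
        for tr, u in zip(traces, a_concs)])
    params = lmfit.Parameters()
    params.add("kp2", value=max(slope0, 1e-6), min=0)
    params.add("B", value=1.0 if fit_burst else 0.0, min=0, vary=fit_burst)
    params.add("tau_b", value=10.0, min=1e-3, vary=fit_burst)

    def residual(p):
        res = []
        for tr, u in zip(traces, a_concs):
            pred = _production_curve(tr.t, alpha2_per_kp2 * p["kp2"].value * u,
                                     p["B"].value, p["tau_b"].value)
            res.append(tr[signal] - pred)
        return np.concatenate(res)

    out = lmfit.minimize(residual, params, method="least_squares")
    est = {n: out.params[n].value for n in ("kp2", "B", "tau_b")}
    return FitResult(
        estimates=est,
        residual_ss=float(np.sum(out.residual**2)),
        converged=bool(out.success),
        stderr={n: out.params[n].stderr for n in est},
        meta={"a_concs": list(map(float, a_concs)),
              "alpha2_per_kp2": alpha2_per_kp2, "fit_burst": fit_burst},
    )


def fit_degradation(trace: Trace, rmg0: float, img0: float,
                    k: Optional[float] = None, signal: str = "rMG") -> FitResult:
    """Fit beta1 and gamma1 from a complex-degradation time course.

    The forward model is the hybridization + degradation mini-system with
    iMG recycling; ``k`` may be supplied from the binding assay or co-fitted.
    The fall of free rMG sets gamma1 (turnover speed) while the level where
    degradation stalls sets beta1 (loss of the catalytic iMG pool).
    """
    if img0 <= 0:
        raise ValueError("img0 = 0: beta1 and gamma1 are not identifiable "
                         "without the degradation pathway")
    y = trace[signal]
    if np.ptp(y) < 1e-9 * max(abs(y).max(), 1.0):
        raise ValueError("flat trace: degradation rates not identifiable")
    co_fit_k = k is None
    params = lmfit.Parameters()
    params.add("beta1", value=0.01, min=1e-8)
    params.add("gamma1", value=0.01, min=1e-8)
    params.add("k", value=k if k is not None else 1e-3, min=1e-8,
               vary=co_fit_k)

    def residual(p):
        series = degradation_mini_model(trace.t, rmg0, img0, p["k"].value,
                                        p["beta1"].value, p["gamma1"].value,
                                        rtol=1e-8, atol=1e-11)
        return series["rMG"] - y

    out = lmfit.minimize(residual, params, method="least_squares")
    names = ["beta1", "gamma1"] + (["k"] if co_fit_k else [])
    return FitResult(
        estimates={n: out.params[n].value for n in names},
        residual_ss=float(np.sum(out.residual**2)),
        converged=bool(out.success),
        stderr={n: out.params[n].stderr for n in names},
        meta={"rmg0": rmg0, "img0": img0, "k_fixed": None if co_fit_k else k},
    )


def default_bounds(init: RateParams) -> Dict[str, Tuple[float, float]]:
    """Search box for the global refinement.

    Production parameters stay within +-30% of their elementary estimates
    (those assays are trusted); binding and degradation constants may move
    a decade either way.
    """
    bounds = {}
    for name in ("kp1", "kp2", "B", "tau_b"):
        v = getattr(init, name)
        if v == 0:
            bounds[name] = (0.0, 1e-12)
        else:
            bounds[name] = (0.7 * v, 1.3 * v)
    for name in ("k", "beta1", "gamma1"):
        v = getattr(init, name)
        bounds[name] = (v / 10.0, v * 10.0)
    return bounds


def _forward_y(theta: np.ndarray, config: CircuitConfig,
               schedule: InputSchedule, t: np.ndarray,
               base: RateParams, sim_opts: SimOptions) -> np.ndarray:
    kp1, kp2, B, tau_b, k, beta1, gamma1 = theta
    rates = base.replace(kp1=kp1, kp2=kp2, B=B, tau_b=max(tau_b, 1e-6),
                         k=k, beta1=beta1, gamma1=gamma1)
    tr = simulate("simple", rates, config, schedule,
                  sim_opts.replace(t_end=float(t[-1])))
    return np.interp(t, tr.t, tr["y"])


def refine_global(traces: Sequence[Tuple[Trace, CircuitConfig, InputSchedule]],
                  init: RateParams,
                  bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                  n_starts: int = 5, seed: int = 0,
                  signal: str = "rMG",
                  sim_opts: Optional[SimOptions] = None) -> FitResult:
    """Global least-squares refinement of the circuit model.

    Fits one shared parameter vector (kp1, kp2, B, tau_b, k, beta1, gamma1)
    to every trace simultaneously, with the three-species model as forward
    operator.  Residuals are weighted per trace by its maximum signal so
    high-amplitude conditions do not dominate.  ``n_starts`` seeded jitters
    of the initial point are run and the best final residual kept; the
    procedure is deterministic for fixed data, init, bounds and seed.
    """
    if not traces:
        raise ValueError("need at least one trace")
    bounds = bounds or default_bounds(init)
    sim_opts = sim_opts or SimOptions(rtol=1e-7, atol=1e-9, grid_dt=2.0)
    names = GLOBAL_PARAM_NAMES
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    x0 = np.clip(np.array([getattr(init, n) for n in names]), lo, hi)
    weights = [1.0 / max(np.abs(tr[signal]).max(), 1e-12)
               for tr, _, _ in traces]

    def residual(theta):
        res = []
        for (tr, cfg, sched), w in zip(traces, weights):
            pred = _forward_y(theta, cfg, sched, tr.t, init, sim_opts)
            res.append(w * (pred - tr[signal]))
        return np.concatenate(res)

    rng = np.random.default_rng(seed)
    starts = [x0]
    for _ in range(max(n_starts - 1, 0)):
        jitter = x0 * np.exp(rng.normal(0.0, 0.1, size=len(x0)))
        starts.append(np.clip(jitter, lo, hi))

    best = None
    for s in starts:
        sol = least_squares(residual, s, bounds=(lo, hi), method="trf",
                            x_scale=np.maximum(np.abs(x0), 1e-12),
                            xtol=1e-10, ftol=1e-10, gtol=1e-10)
        if best is None or sol.cost < best.cost:
            best = sol

    estimates = dict(zip(names, best.x))
    # covariance-based uncertainties from the final Jacobian where possible
    stderr: Dict[str, Optional[float]] = {n: None for n in names}
    try:
        J = best.jac
        dof = max(len(best.fun) - len(names), 1)
        s2 = 2 * best.cost / dof
        cov = s2 * np.linalg.pinv(J.T @ J)
        for i, n in enumerate(names):
            stderr[n] = float(np.sqrt(max(cov[i, i], 0.0)))
    except np.linalg.LinAlgError:
        pass

    result = FitResult(
        estimates=estimates,
        residual_ss=float(2 * best.cost),
        converged=bool(best.status > 0),
        stderr=stderr,
        bounds_used={n: (float(a), float(b)) for n, a, b in zip(names, lo, hi)},
        meta={"n_traces": len(traces), "n_starts": n_starts, "seed": seed,
              "per_trace_weights": weights, "optimizer_status": int(best.status)},
    )
    pinned = result.at_bound()
    if pinned:
        result.warnings.append(f"parameters at bounds: {', '.join(pinned)}")
    return result


def refined_rates(result: FitResult, base: RateParams) -> RateParams:
    """RateParams with the globally refined estimates substituted in."""
    return base.replace(**{n: result.estimates[n] for n in GLOBAL_PARAM_NAMES
                           if n in result.estimates})
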