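"""Model/Results front end for fitting the adapter circuit to trace data.

:class:`AdapterCircuitModel` is constructed from observed rMG traces (one
per reaction condition) and fits the shared kinetic parameter vector of the
three-species IFFL model by bounded nonlinear least squares; ``fit()``
returns an :class:`AdapterCircuitResults` carrying estimates, standard
errors, diagnostics and a ``summary()`` table, with simulation of the
fitted circuit hanging off the results object.
"""

from __future__ import annotations

from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .circuit_models import simulate
from .fitting import (GLOBAL_PARAM_NAMES, FitResult, default_bounds,
                      refine_global, refined_rates)
from .params import CircuitConfig, RateParams, derived_rates
from .schedule import InputSchedule
from .steady_state import equilibrium_simple, nondimensionalize
from .trace import SimOptions, Trace


class AdapterCircuitModel:
    """Three-species IFFL circuit model bound to observed traces.

    Parameters
    ----------
    traces
        Sequence of ``(trace, config, schedule)`` triples; each trace must
        carry an rMG concentration series (nM).
    init
        Starting parameter set, typically from the elementary-reaction fits.
    bounds
        Optional per-parameter (lo, hi) mapping; defaults to a narrow box
        around ``init`` for the transcription parameters and a decade for
        binding/degradation.
    """

    def __init__(self, traces: Sequence[Tuple[Trace, CircuitConfig, InputSchedule]],
                 init: RateParams,
                 bounds: Optional[Dict[str, Tuple[float, float]]] = None,
                 signal: str = "rMG"):
        if not traces:
            raise ValueError("need at least one observed trace")
        self.traces = list(traces)
        self.init = init
        self.bounds = bounds or default_bounds(init)
        self.signal = signal

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, conditions: Sequence[dict],
                       init: RateParams, **kwargs) -> "AdapterCircuitModel":
        """Build from a long-format frame with columns (condition, t, rMG).

        ``conditions[i]`` must provide ``config`` (:class:`CircuitConfig`)
        and ``schedule`` (:class:`InputSchedule`) for condition label i.
        """
        triples = []
        for i, cond in enumerate(conditions):
            sub = df[df["condition"] == i].sort_values("t")
            tr = Trace(sub["t"].to_numpy(), {"rMG": sub["rMG"].to_numpy()},
                       {"condition": i})
            triples.append((tr, cond["config"], cond["schedule"]))
        return cls(triples, init, **kwargs)

    def fit(self, n_starts: int = 5, seed: int = 0,
            sim_opts: Optional[SimOptions] = None) -> "AdapterCircuitResults":
        res = refine_global(self.traces, self.init, self.bounds,
                            n_starts=n_starts, seed=seed, signal=self.signal,
                            sim_opts=sim_opts)
        return AdapterCircuitResults(self, res)

    def simulate(self, rates: RateParams, index: int = 0,
                 options: Optional[SimOptions] = None) -> Trace:
        """Forward-simulate one of the bound conditions at given rates."""
        tr, cfg, sched = self.traces[index]
        options = options or SimOptions(t_end=float(tr.t[-1]), grid_dt=1.0)
        return simulate("simple", rates, cfg, sched, options)


class AdapterCircuitResults:
    """Fitted parameters with uncertainties and model-level diagnostics."""

    def __init__(self, model: AdapterCircuitModel, fit_result: FitResult):
        self.model = model
        self.fit_result = fit_result
        self.params = dict(fit_result.estimates)
        self.bse = dict(fit_result.stderr)
        self.residual_ss = fit_result.residual_ss
        self.converged = fit_result.converged

    @property
    def rates(self) -> RateParams:
        return refined_rates(self.fit_result, self.model.init)

    def predict(self, index: int = 0,
                options: Optional[SimOptions] = None) -> Trace:
        return self.model.simulate(self.rates, index, options)

    def resid(self, index: int = 0) -> np.ndarray:
        tr, _, _ = self.model.traces[index]
        pred = self.predict(index)
        return tr[self.model.signal] - np.interp(tr.t, pred.t, pred["y"])

    def per_trace_rss(self) -> pd.Series:
        return pd.Series({i: float(np.sum(self.resid(i)**2))
                          for i in range(len(self.model.traces))},
                         name="rss")

    def equilibrium(self, index: int = 0, u: float = 1.0):
        _, cfg, _ = self.model.traces[index]
        return equilibrium_simple(derived_rates(cfg, self.rates),
                                  self.rates.k, u)

    def nondim(self, u0: float, index: int = 0):
        _, cfg, _ = self.model.traces[index]
        return nondimensionalize(derived_rates(cfg, self.rates),
                                 self.rates.k, u0)

    def summary(self) -> str:
        units = {"kp1": "1/min", "kp2": "1/min", "B": "-", "tau_b": "min",
                 "k": "1/(nM min)", "beta1": "1/min", "gamma1": "1/min"}
        lines = [
            "Adapter circuit (IFFL) nonlinear least-squares fit",
            "=" * 58,
            f"traces: {len(self.model.traces)}   "
            f"converged: {self.converged}   "
            f"weighted RSS: {self.residual_ss:.4g}",
            "-" * 58,
            f"{'param':>8} {'estimate':>12} {'std err':>12} {'unit':>12}",
        ]
        for name in GLOBAL_PARAM_NAMES:
            se = self.bse.get(name)
            se_s = f"{se:.3g}" if se is not None else "--"
            lines.append(f"{name:>8} {self.params[name]:>12.5g} {se_s:>12} "
                         f"{units[name]:>12}")
        pinned = self.fit_result.at_bound()
        if pinned:
            lines.append(f"note: at bounds: {', '.join(pinned)}")
        lines.append("=" * 58)
        return "\n".join(lines)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "estimate": pd.Series(self.params),
            "std_err": pd.Series(self.bse),
        })
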