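"""Pulse-response metrics and (p1, p2) phase-space sweeps of the dimensionless model.

The standard perturbation: all scaled variables start at their steady value
1, and the input steps from 1 to ``fold`` at ``t = 1`` (scaled time).  Four
metrics summarize each response:

* ``A`` -- pulse amplitude, ``max(y) - 1``;
* ``T`` -- adaptation time, the earliest T such that ``y(t > T)`` stays in
  the band [0.99, 1.01];
* ``R`` -- amplitude ratio ``A2/A1`` between the response at ``p2`` and the
  response at ``2*p2`` (i.e. the same fold applied from a doubled
  baseline) -- equal to 1 under perfect fold-change detection;
* ``E`` -- normalized error between the two traces,
  ``int_{1}^{T1} |y1 - y2| dt / (A1 * T1)``.

The fold-change-detection limit (small p1, large p2) reduces to
``dX/dt = F - X, y = F/X``, whose response depends only on the input fold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .circuit_models import simulate
from .schedule import InputSchedule
from .trace import SimOptions, Trace

BAND = (0.99, 1.01)
_DEFAULT_GRID_DT = 0.01


@dataclass(frozen=True)
class PulseMetrics:
    A: float                      # amplitude, max(y) - 1
    T: float                      # adaptation time (scaled)
    R: Optional[float] = None     # amplitude ratio A2/A1
    E: Optional[float] = None     # normalized trace error


class NotSettledError(RuntimeError):
    """Trace did not re-enter the adaptation band before t_end."""


def pulse_trace(p: Tuple[float, float, float], fold: float = 2.0,
                t_step: float = 1.0, t_end: Optional[float] = None,
                grid_dt: float = _DEFAULT_GRID_DT) -> Trace:
    """Simulate the standard pulse perturbation of the dimensionless model.

    Starts from the scaled steady state (1, 1, 1) with u = 1 and steps the
    input to ``fold`` at ``t_step``.  If ``t_end`` is not given, the run is
    extended (doubling from 50) until the output has settled back into the
    adaptation band, up to a hard cap.
    """
    p1, p2, p3 = p
    if min(p1, p2, p3) <= 0:
        raise ValueError("p1, p2, p3 must be positive")
    if fold <= 0:
        raise ValueError("fold must be positive")
    sched = InputSchedule.from_totals([0.0, t_step], [1.0, fold])

    def run(te: float) -> Trace:
        return simulate("nondim", schedule=sched, nondim=(p1, p2, p3),
                        options=SimOptions(t_end=te, grid_dt=grid_dt),
                        initial_state=(1.0, 1.0, 1.0))

    if t_end is not None:
        return run(t_end)
    te = 50.0
    while True:
        tr = run(te)
        tail = tr["y"][tr.t >= te - 5.0]
        if np.all((tail > BAND[0]) & (tail < BAND[1])):
            return tr
        te *= 2
        if te > 12800:
            raise NotSettledError(
                f"pulse at p=({p1:g},{p2:g},{p3:g}) fold={fold:g} "
                f"not settled by t={te / 2:g}")


def pulse_metrics(trace: Trace, t_step: float = 1.0,
                  band: Tuple[float, float] = BAND) -> PulseMetrics:
    """Amplitude and adaptation time of a single pulse trace.

    ``A`` is taken from the dense maximum after the step; ``T`` by scanning
    backward from the end of the trace for the last excursion outside the
    band (robust against transient re-entries).
    """
    t, y = trace.t, trace["y"]
    after = t >= t_step
    A = float(y[after].max() - 1.0)
    outside = (y < band[0]) | (y > band[1])
    if outside[-1]:
        raise NotSettledError("T undefined before t_end: trace ends outside band")
    idx = np.nonzero(outside)[0]
    if len(idx) == 0:
        T = t_step  # never left the band
    else:
        T = float(t[idx[-1]])
    return PulseMetrics(A=A, T=max(T, t_step))


def fcd_pair_metrics(p1: float, p2: float, p3: float, fold: float = 2.0,
                     t_step: float = 1.0,
                     grid_dt: float = _DEFAULT_GRID_DT) -> PulseMetrics:
    """Fold-change-detection metrics for the pair (p2, 2*p2).

    Compares the pulse at ``(p1, p2)`` with the pulse at ``(p1, 2*p2)`` --
    the same input fold applied from a doubled baseline.  Returns all four
    metrics, with R and E measuring how close the pair is to perfect
    fold-change detection.
    """
    tr1 = pulse_trace((p1, p2, p3), fold, t_step, grid_dt=grid_dt)
    tr2 = pulse_trace((p1, 2.0 * p2, p3), fold, t_step, grid_dt=grid_dt)
    t_end = max(tr1.t[-1], tr2.t[-1])
    if tr1.t[-1] < t_end:
        tr1 = pulse_trace((p1, p2, p3), fold, t_step, t_end=t_end, grid_dt=grid_dt)
    if tr2.t[-1] < t_end:
        tr2 = pulse_trace((p1, 2.0 * p2, p3), fold, t_step, t_end=t_end,
                          grid_dt=grid_dt)
    m1 = pulse_metrics(tr1, t_step)
    m2 = pulse_metrics(tr2, t_step)
    if m1.A <= 0:
        raise ValueError("A1 = 0: ratio metrics undefined")
    window = (tr1.t >= t_step) & (tr1.t <= m1.T)
    E = float(np.trapezoid(np.abs(tr1["y"][window] - tr2["y"][window]),
                           tr1.t[window]) / (m1.A * m1.T))
    return PulseMetrics(A=m1.A, T=m1.T, R=m2.A / m1.A, E=E)


@dataclass
class SweepResult:
    """Metric matrices over a (p1, p2) grid at fixed p3 (rows: p1, cols: p2)."""

    p1_grid: np.ndarray
    p2_grid: np.ndarray
    A: np.ndarray
    T: np.ndarray
    R: np.ndarray
    E: np.ndarray
    p3: float
    failed: np.ndarray  # boolean mask of non-converged cells

    def to_frames(self) -> dict:
        idx = pd.Index(self.p1_grid, name="p1")
        cols = pd.Index(self.p2_grid, name="p2")
        return {m: pd.DataFrame(getattr(self, m), index=idx, columns=cols)
                for m in ("A", "T", "R", "E")}

    def save(self, outdir) -> None:
        from pathlib import Path
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, df in self.to_frames().items():
            df.to_csv(outdir / f"sweep_{name}.csv")


def sweep(p1_values: Optional[Sequence[float]] = None,
          p2_values: Optional[Sequence[float]] = None,
          p3: float = 1.0, fold: float = 2.0,
          grid_dt: float = _DEFAULT_GRID_DT) -> SweepResult:
    """Map the four pulse metrics over a (p1, p2) grid.

    Defaults to log-spaced grids p1 in [1e-2, 1e1] and p2 in [1e-1, 1e2]
    (5 points each).  Individual cell failures are flagged, not fatal.
    """
    p1_values = (np.asarray(p1_values, float) if p1_values is not None
                 else np.logspace(-2, 1, 5))
    p2_values = (np.asarray(p2_values, float) if p2_values is not None
                 else np.logspace(-1, 2, 5))
    if (p1_values <= 0).any() or (p2_values <= 0).any():
        raise ValueError("grids must be positive")
    shape = (len(p1_values), len(p2_values))
    mats = {m: np.full(shape, np.nan) for m in ("A", "T", "R", "E")}
    failed = np.zeros(shape, dtype=bool)
    for i, p1 in enumerate(p1_values):
        for j, p2 in enumerate(p2_values):
            try:
                m = fcd_pair_metrics(p1, p2, p3, fold, grid_dt=grid_dt)
            except (NotSettledError, ValueError):
                failed[i, j] = True
                continue
            mats["A"][i, j] = m.A
            mats["T"][i, j] = m.T
            mats["R"][i, j] = m.R
            mats["E"][i, j] = m.E
    return SweepResult(p1_values, p2_values, mats["A"], mats["T"],
                       mats["R"], mats["E"], p3, failed)


def fcd_limit_trace(F_schedule: InputSchedule, t_end: float,
                    grid_dt: float = _DEFAULT_GRID_DT) -> Trace:
    """Integrate the fold-change-detection limit model under a step protocol.

    The input schedule is interpreted through its running total; the model
    sees only folds relative to the initial level, so any uniform rescaling
    of the schedule leaves the output unchanged.
    """
    return simulate("fcd_limit", schedule=F_schedule,
                    options=SimOptions(t_end=t_end, grid_dt=grid_dt))
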