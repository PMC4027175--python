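"""Time-series container and CSV round-trip for simulated and measured signals."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np
import pandas as pd


@dataclass
class Trace:
    """Uniformly or event-sampled time series of named species/signals.

    ``t`` is strictly increasing; every series has the same length as ``t``.
    ``meta`` carries model kind, units, schedule and seed information and is
    preserved through the CSV round-trip.
    """

    t: np.ndarray
    series: Dict[str, np.ndarray]
    meta: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        if self.t.ndim != 1:
            raise ValueError("t must be one-dimensional")
        if len(self.t) > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("t must be strictly increasing")
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        for name, v in self.series.items():
            if v.shape != self.t.shape:
                raise ValueError(f"series {name!r} length {len(v)} != len(t) {len(self.t)}")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.series[name]

    def __contains__(self, name: str) -> bool:
        return name in self.series

    @property
    def names(self):
        return list(self.series)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t": self.t, **self.series})

    def with_series(self, **extra: np.ndarray) -> "Trace":
        new = dict(self.series)
        new.update(extra)
        return Trace(self.t.copy(), new, dict(self.meta))

    def slice(self, t0: float, t1: float) -> "Trace":
        """Sub-trace on the closed window [t0, t1]."""
        mask = (self.t >= t0) & (self.t <= t1)
        return Trace(self.t[mask], {k: v[mask] for k, v in self.series.items()},
                     dict(self.meta))

    def to_csv(self, path) -> None:
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# meta: " + json.dumps(self.meta, default=str) + "\n")
            self.to_frame().to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "Trace":
        path = Path(path)
        meta: Dict = {}
        with path.open() as fh:
            first = fh.readline()
            if first.startswith("# meta:"):
                meta = json.loads(first[len("# meta:"):])
                df = pd.read_csv(fh)
            else:
                fh.seek(0)
                df = pd.read_csv(fh, comment="#")
        t = df["t"].to_numpy()
        series = {c: df[c].to_numpy() for c in df.columns if c != "t"}
        return cls(t, series, meta)


@dataclass(frozen=True)
class SimOptions:
    """Integrator and sampling settings.

    Defaults favour accuracy over speed: the binding step ``k*x*y`` is fast
    against the slow degradation constants, so the system is stiff.
    """

    t_end: float = 600.0           # min (or scaled time)
    rtol: float = 1e-8
    atol: float = 1e-10            # nM
    max_step: float = np.inf
    grid_dt: float = 0.1           # output grid spacing
    steady_state_band: float = 0.01
    method: str = "LSODA"

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        if self.rtol <= 0 or self.atol <= 0 or self.grid_dt <= 0:
            raise ValueError("tolerances and grid spacing must be positive")

    def replace(self, **changes) -> "SimOptions":
        from dataclasses import replace as _replace
        return _replace(self, **changes)
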