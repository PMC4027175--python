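"""Structured run-configuration files (YAML) and their object mapping.

A run config has sections::

    model: simple | mm | nondim | detailed | fcd_limit
    rates: {kp1: ..., kp2: ..., k: ..., beta1: ..., gamma1: ..., ...}
    config: {TrMG_tot: ..., TiMG_tot: ..., rnap: ..., rnase_r: ...}
    nondim: {p1: ..., p2: ..., p3: ..., u0: ...}          # nondim runs
    schedule:
      - {time: 0, species: A, amount: 10}
    sim: {t_end: 420, grid_dt: 0.5, rtol: 1e-8, atol: 1e-10}
    protocol: {name: fold_change, ...}                     # optional

The mapping is a deterministic round trip: dumping a loaded config
reproduces the same objects.
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Optional

import yaml

from .params import CircuitConfig, NondimParams, RateParams
from .schedule import InputEvent, InputSchedule
from .trace import SimOptions


class RunConfig:
    def __init__(self, model: str = "simple",
                 rates: Optional[RateParams] = None,
                 config: Optional[CircuitConfig] = None,
                 nondim: Optional[NondimParams] = None,
                 schedule: Optional[InputSchedule] = None,
                 sim: Optional[SimOptions] = None,
                 protocol: Optional[dict] = None):
        self.model = model
        self.rates = rates
        self.config = config
        self.nondim = nondim
        self.schedule = schedule or InputSchedule()
        self.sim = sim or SimOptions()
        self.protocol = protocol or {}

    def to_dict(self) -> dict:
        d: dict = {"model": self.model}
        if self.rates is not None:
            d["rates"] = asdict(self.rates)
        if self.config is not None:
            d["config"] = asdict(self.config)
        if self.nondim is not None:
            d["nondim"] = asdict(self.nondim)
        d["schedule"] = [{"time": e.time, "species": e.species,
                          "amount": e.amount} for e in self.schedule.events]
        d["sim"] = asdict(self.sim)
        if self.protocol:
            d["protocol"] = self.protocol
        return d


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    rates = RateParams(**raw["rates"]) if "rates" in raw else None
    config = CircuitConfig(**raw["config"]) if "config" in raw else None
    nondim = NondimParams(**raw["nondim"]) if "nondim" in raw else None
    schedule = InputSchedule(tuple(
        InputEvent(ev["time"], ev["species"], ev["amount"])
        for ev in raw.get("schedule", [])))
    sim = SimOptions(**raw["sim"]) if "sim" in raw else SimOptions()
    return RunConfig(raw.get("model", "simple"), rates, config, nondim,
                     schedule, sim, raw.get("protocol"))


def dump_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
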