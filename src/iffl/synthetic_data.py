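"""Synthetic spectrofluorometer data with known ground truth.

Emulates what the instrument records in the wet experiments: the
malachite-green fluorescence of free rMG, linearly calibrated to
concentration, on top of a slowly bleaching free-dye background
(pseudo-first-order decay) and additive Gaussian read noise, sampled once
per minute.  Three elementary-reaction assays are generated alongside the
full-circuit measurement so the estimation pipeline can be exercised end to
end against known parameters:

* transcription assays (production-only genelet at several activator
  levels, with the burst phase);
* the rMG/iMG hybridization assay (equal-concentration second-order decay);
* the RNase-R degradation assay (complex degradation with iMG recycling).

Every generator returns the noisy raw trace together with its noise-free
ground truth; downstream fits consume only the raw trace.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .circuit_models import simulate
from .params import CircuitConfig, RateParams, derived_rates
from .schedule import InputSchedule
from .trace import SimOptions, Trace


@dataclass(frozen=True)
class MeasurementModel:
    """Forward model of the fluorescence measurement.

    raw(t) = fluor_per_nM * [rMG](t) + bleach_amp * exp(-bleach_rate * t)
             + N(0, noise_sd)

    Noise is additive on the fluorescence scale only.
    """

    fluor_per_nM: float = 1.0     # a.u. per nM of free rMG
    bleach_rate: float = 0.002    # 1/min, pseudo-first-order dye bleaching
    bleach_amp: float = 0.0       # a.u., initial free-dye background
    noise_sd: float = 0.0         # a.u.
    sample_dt: float = 1.0        # min
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fluor_per_nM <= 0:
            raise ValueError("fluor_per_nM must be positive")
        if self.noise_sd < 0 or self.sample_dt <= 0 or self.bleach_rate < 0:
            raise ValueError("invalid measurement parameters")

    def apply(self, t: np.ndarray, conc: np.ndarray,
              rng: Optional[np.random.Generator] = None) -> np.ndarray:
        rng = rng or np.random.default_rng(self.seed)
        raw = (self.fluor_per_nM * conc
               + self.bleach_amp * np.exp(-self.bleach_rate * t))
        if self.noise_sd > 0:
            raw = raw + rng.normal(0.0, self.noise_sd, size=raw.shape)
        return raw


def _sample_grid(t_end: float, dt: float) -> np.ndarray:
    return np.arange(0.0, t_end + dt / 2, dt)


def gen_circuit_assay(rates: RateParams, config: CircuitConfig,
                      schedule: InputSchedule, mm: MeasurementModel,
                      t_end: float = 420.0,
                      model_kind: str = "simple") -> Tuple[Trace, Trace]:
    """Full-circuit measurement: returns (raw fluorescence, ground truth).

    Ground truth is the noise-free simulated trace (all species, nM); the
    raw trace carries the fluorescence series sampled at ``sample_dt``.
    """
    opts = SimOptions(t_end=t_end, grid_dt=mm.sample_dt)
    truth = simulate(model_kind, rates, config, schedule, opts)
    t = _sample_grid(t_end, mm.sample_dt)
    y = np.interp(t, truth.t, truth["y"])
    raw = mm.apply(t, y, np.random.default_rng(mm.seed))
    meta = {"assay": "circuit", "seed": mm.seed, "units": "a.u.",
            "measurement": mm.__dict__.copy(),
            "schedule": [(e.time, e.species, e.amount) for e in schedule.events]}
    return Trace(t, {"fluor": raw}, meta), truth


def gen_blank_assay(mm: MeasurementModel, t_end: float = 420.0) -> Trace:
    """Signal-free blank measurement: bleaching background plus noise only.

    Mirrors the separate bleaching characterization used to calibrate the
    background correction.
    """
    t = _sample_grid(t_end, mm.sample_dt)
    raw = mm.apply(t, np.zeros_like(t))
    return Trace(t, {"fluor": raw},
                 {"assay": "blank", "seed": mm.seed,
                  "truth": {"bleach_amp": mm.bleach_amp,
                            "bleach_rate": mm.bleach_rate}})


def binding_decay(t: np.ndarray, k: float, c0: float) -> np.ndarray:
    """Equal-concentration second-order decay c(t) = 1/(k t + 1/c0)."""
    return 1.0 / (k * t + 1.0 / c0)


def gen_binding_assay(c0: float, k: float, mm: MeasurementModel,
                      t_end: float = 120.0) -> Tuple[Trace, Trace]:
    """Hybridization assay: equal amounts of iMG added to rMG.

    With [rMG](0) = [iMG](0) = c0 and irreversible second-order annihilation
    the free rMG follows ``c(t) = 1/(k t + 1/c0)`` (reciprocal intercept
    1/c0).  Returns (raw fluorescence trace, ground-truth concentration).
    """
    if c0 <= 0:
        raise ValueError("c0 must be positive")
    t = _sample_grid(t_end, mm.sample_dt)
    conc = binding_decay(t, k, c0)
    raw = mm.apply(t, conc)
    meta = {"assay": "binding", "c0_nM": c0, "k_true": k, "seed": mm.seed}
    return (Trace(t, {"fluor": raw}, meta),
            Trace(t, {"rMG": conc}, dict(meta, units="nM")))


def gen_transcription_assay(a_concs: Sequence[float], rates: RateParams,
                            config: CircuitConfig, mm: MeasurementModel,
                            t_end: float = 120.0) -> Tuple[list, list]:
    """Production-only assay at several activator levels.

    The rMG template alone is present, so output accumulates as
    ``dy/dt = alpha2 * u * (1 + B exp(-t/tau_b))`` with closed form
    ``y(t) = alpha2*u*(t + B*tau_b*(1 - exp(-t/tau_b)))``.  The long-run
    slope is linear in the activator concentration.  Returns parallel lists
    of raw and ground-truth traces.
    """
    total = config.TrMG_tot + config.TiMG_tot
    if any(a > total for a in a_concs):
        raise ValueError("activator must not exceed total template "
                         "(production is linear in A_tot only below saturation)")
    dr = derived_rates(config, rates)
    t = _sample_grid(t_end, mm.sample_dt)
    raws, truths = [], []
    for i, u in enumerate(a_concs):
        if rates.B > 0:
            y = dr.alpha2 * u * (t + rates.B * rates.tau_b
                                 * (1.0 - np.exp(-t / rates.tau_b)))
        else:
            y = dr.alpha2 * u * t
        rng = np.random.default_rng(mm.seed + i)
        raw = mm.apply(t, y, rng)
        meta = {"assay": "transcription", "A_tot_nM": float(u),
                "seed": mm.seed + i,
                "truth": {"alpha2": dr.alpha2, "B": rates.B, "tau_b": rates.tau_b}}
        raws.append(Trace(t, {"fluor": raw}, meta))
        truths.append(Trace(t, {"rMG": y}, dict(meta, units="nM")))
    return raws, truths


def degradation_mini_model(t: np.ndarray, rmg0: float, img0: float,
                           k: float, beta1: float, gamma1: float,
                           rtol: float = 1e-9, atol: float = 1e-12) -> dict:
    """Hybridization + RNase-R degradation with iMG recycling.

    Species: free rMG (r), free iMG (i), complex (c).  rMG within the
    complex is degraded at ``gamma1``, releasing the iMG strand to bind
    another rMG; free iMG is degraded at ``beta1``; free rMG is stable
    (beta2 = 0) and iMG within the complex is protected (gamma2 = 0).
    Returns dense series for r, i, c and the cumulative rMG degraded.
    """

    def rhs(_t, s):
        r, i, c, deg = s
        bind = k * r * i
        return (-bind, -bind + gamma1 * c - beta1 * i,
                bind - gamma1 * c, gamma1 * c)

    sol = solve_ivp(rhs, (t[0], t[-1]), [rmg0, img0, 0.0, 0.0],
                    t_eval=t, method="LSODA", rtol=rtol, atol=atol)
    if not sol.success:
        raise RuntimeError(f"degradation mini-model failed: {sol.message}")
    r, i, c, deg = sol.y
    return {"rMG": r, "iMG": i, "complex": c, "rMG_degraded": deg}


def gen_degradation_assay(rmg0: float, img0: float, rnase_r: float,
                          rates: RateParams, mm: MeasurementModel,
                          t_end: float = 240.0,
                          rnase_r_ref: float = 75.0) -> Tuple[Trace, Trace]:
    """Degradation assay: RNase R added to a pre-mixed rMG/iMG pool.

    With substoichiometric iMG, complex degradation recycles iMG so the
    total rMG degraded exceeds the iMG amount (catalytic turnover); free
    rMG alone is not degraded.  Degradation rates scale linearly with
    [RNase R] relative to the calibration reference.
    """
    if rmg0 < 0 or img0 < 0:
        raise ValueError("initial concentrations must be nonnegative")
    scale = rnase_r / rnase_r_ref if rnase_r_ref > 0 else 0.0
    t = _sample_grid(t_end, mm.sample_dt)
    series = degradation_mini_model(t, rmg0, img0, rates.k,
                                    rates.beta1 * scale, rates.gamma1 * scale)
    raw = mm.apply(t, series["rMG"])
    meta = {"assay": "degradation", "rmg0_nM": rmg0, "img0_nM": img0,
            "rnase_r_nM": rnase_r, "seed": mm.seed,
            "truth": {"k": rates.k, "beta1": rates.beta1 * scale,
                      "gamma1": rates.gamma1 * scale}}
    return (Trace(t, {"fluor": raw}, meta),
            Trace(t, dict(series), dict(meta, units="nM")))
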