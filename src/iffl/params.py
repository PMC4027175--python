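"""Kinetic parameters and reaction conditions for the transcriptional adapter circuit.

The circuit is an incoherent feed-forward loop (IFFL) built from two genelet
switches: a DNA activator strand A (the input ``u``) switches on both the
template producing the malachite-green reporter aptamer rMG (the output ``y``)
and the template producing the RNA inhibitor iMG (the repressor ``x``), which
sequesters rMG into a dark rMG.iMG complex (``z``).  RNase R provides tunable
first-order degradation of iMG and of rMG within the complex.

Two kinds of parameters are kept separate:

* :class:`RateParams` -- intrinsic rate constants of the molecular reactions,
  calibrated at reference enzyme concentrations.
* :class:`CircuitConfig` -- the composition of a particular reaction mix
  (template and enzyme concentrations).

:func:`derived_rates` combines the two into the effective production and
degradation coefficients of the three-species ODE model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class RateParams:
    """Rate constants of the adapter circuit.

    Parameters
    ----------
    kp1 : float
        Transcription rate constant feeding iMG production (1/min).
    kp2 : float
        Transcription rate constant feeding rMG production (1/min).
    B : float
        Burst magnitude: dimensionless excess of the initial transcription
        rate over the steady rate, ``kp2_burst(0) = kp2 * (1 + B)``.
    tau_b : float
        Burst decay time constant (min).
    k_plus : float
        Template--activator hybridization rate constant (1/(nM min)); only
        used by the detailed model with explicit template states.
    k : float
        rMG.iMG hybridization (toehold-mediated) rate constant (1/(nM min)).
    beta1 : float
        Degradation rate constant of free iMG by RNase R (1/min).
    beta2 : float
        Degradation rate constant of free rMG (1/min); the reporter carries a
        single unpaired 3' base, so this is negligible (default 0).
    gamma1 : float
        Degradation rate constant of rMG within the rMG.iMG complex (1/min);
        degradation releases the iMG strand for further catalysis.
    gamma2 : float
        Degradation rate constant of iMG within the complex (1/min); the
        complex hides the iMG 3' end, so this is negligible (default 0).
    K_M : float
        RNAP Michaelis constant (nM), used by the saturating variant.
    K_M_R_x : float
        RNase R Michaelis constant for free iMG (nM).
    K_M_R_z : float
        RNase R Michaelis constant for the rMG.iMG complex (nM).
    """

    kp1: float
    kp2: float
    k: float
    beta1: float
    gamma1: float
    B: float = 0.0
    tau_b: float = 1.0
    k_plus: float = 1e-2
    beta2: float = 0.0
    gamma2: float = 0.0
    K_M: float = 1e6
    K_M_R_x: float = 1e6
    K_M_R_z: float = 1e6

    def __post_init__(self) -> None:
        for name in ("kp1", "kp2", "k", "beta1", "gamma1", "B", "tau_b",
                     "k_plus", "beta2", "gamma2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative, got {getattr(self, name)}")
        if self.B != 0 and self.tau_b <= 0:
            raise ValueError("tau_b must be positive when B != 0")
        for name in ("K_M", "K_M_R_x", "K_M_R_z"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def replace(self, **changes) -> "RateParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class CircuitConfig:
    """Composition of one reaction mix.

    ``rnap_ref`` and ``rnase_r_ref`` are the enzyme concentrations at which
    the :class:`RateParams` were calibrated; transcription rates scale
    linearly with [RNAP]/[RNAP]_ref and degradation rates with
    [RNase R]/[RNase R]_ref.
    """

    TrMG_tot: float  # total rMG-template concentration (nM)
    TiMG_tot: float  # total iMG-template concentration (nM)
    rnap: float = 171.0
    rnase_r: float = 75.0
    rnap_ref: float = 171.0
    rnase_r_ref: float = 75.0

    def __post_init__(self) -> None:
        for name in ("TrMG_tot", "TiMG_tot", "rnap", "rnase_r",
                     "rnap_ref", "rnase_r_ref"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if self.TrMG_tot + self.TiMG_tot <= 0:
            raise ValueError("total template concentration must be positive")

    @property
    def template_ratio(self) -> float:
        if self.TiMG_tot == 0:
            raise ZeroDivisionError("template ratio undefined for TiMG_tot=0")
        return self.TrMG_tot / self.TiMG_tot

    def replace(self, **changes) -> "CircuitConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class DerivedRates:
    """Effective coefficients of the three-species model.

    ``alpha1`` and ``alpha2`` are per-input production coefficients: each
    template family claims a share of the activator input proportional to its
    fraction of total template, so

    ``alpha1 = kp1 * TiMG_tot / (TrMG_tot + TiMG_tot)`` and
    ``alpha2 = kp2 * TrMG_tot / (TrMG_tot + TiMG_tot)``,

    both multiplied by [RNAP]/[RNAP]_ref.  ``beta1_eff`` and ``gamma1_eff``
    are the RNase-R-scaled degradation constants.
    """

    alpha1: float
    alpha2: float
    beta1_eff: float
    gamma1_eff: float


def derived_rates(config: CircuitConfig, rates: RateParams) -> DerivedRates:
    """Map rate constants and a reaction mix to effective model coefficients.

    Raises
    ------
    ValueError
        If a reference enzyme concentration is zero while the corresponding
        enzyme is present (the linear scaling would be undefined).
    """
    total = config.TrMG_tot + config.TiMG_tot
    if total <= 0:
        raise ValueError("total template concentration must be positive")
    if config.rnap > 0 and config.rnap_ref <= 0:
        raise ValueError("rnap_ref must be positive when rnap > 0")
    if config.rnase_r > 0 and config.rnase_r_ref <= 0:
        raise ValueError("rnase_r_ref must be positive when rnase_r > 0")
    rnap_scale = config.rnap / config.rnap_ref if config.rnap_ref > 0 else 0.0
    rnase_scale = (config.rnase_r / config.rnase_r_ref
                   if config.rnase_r_ref > 0 else 0.0)
    return DerivedRates(
        alpha1=rates.kp1 * config.TiMG_tot / total * rnap_scale,
        alpha2=rates.kp2 * config.TrMG_tot / total * rnap_scale,
        beta1_eff=rates.beta1 * rnase_scale,
        gamma1_eff=rates.gamma1 * rnase_scale,
    )


@dataclass(frozen=True)
class NondimParams:
    """Dimensionless parameter triple of the rescaled adapter model.

    ``p1 = alpha2/alpha1`` (relative strength of the output branch),
    ``p2 = k*alpha1*u0/beta1**2`` (speed of output sequestration relative to
    repressor turnover at baseline input ``u0``), and ``p3 = gamma1/beta1``
    (complex vs free-repressor degradation).  Time is measured in units of
    ``tau = beta1 * t``.
    """

    p1: float
    p2: float
    p3: float
    u0: float

    def __post_init__(self) -> None:
        if self.p1 <= 0 or self.p2 <= 0 or self.p3 <= 0:
            raise ValueError("p1, p2, p3 must be positive")
        if self.u0 <= 0:
            raise ValueError("u0 must be positive")


# Representative operating point of the adapter circuit used throughout the
# examples and protocol defaults.  The rate magnitudes are synthetic but
# chosen to be physically plausible for T7 genelet circuits (transcription
# ~1e-2/min per activated template, strand hybridization ~1e5/M/s, RNase R
# turnover ~1e-2/min) and, at the fold-change-detection reaction conditions
# (TrMG 50 nM, TiMG 150 nM, u0 = 10 nM), to sit at the dimensionless
# operating point p1 = 0.19, p2 = 0.93, p3 = 0.61.
REPRESENTATIVE_RATES = RateParams(
    kp1=0.02,
    kp2=0.0114,          # = 0.19 * 3 * kp1 at template ratio 50:150
    k=5.58e-3,           # = 0.93 * beta1**2 / (alpha1 * u0)
    beta1=0.03,
    gamma1=0.0183,       # = 0.61 * beta1
    B=3.0,
    tau_b=15.0,
    k_plus=1e-2,
)

FCD_CONFIG = CircuitConfig(TrMG_tot=50.0, TiMG_tot=150.0)
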