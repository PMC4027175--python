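import numpy as np
import pytest

from iffl import (FCD_CONFIG, REPRESENTATIVE_RATES, CircuitConfig,
                  InputSchedule, MeasurementModel, RateParams, derived_rates)


@pytest.fixture
def rates() -> RateParams:
    return REPRESENTATIVE_RATES


@pytest.fixture
def rates_noburst() -> RateParams:
    return REPRESENTATIVE_RATES.replace(B=0.0)


@pytest.fixture
def config() -> CircuitConfig:
    return FCD_CONFIG


@pytest.fixture
def unit_rates() -> RateParams:
    """All unit coefficients: alpha1 = alpha2 = beta1 = gamma1 = k = 1."""
    return RateParams(kp1=2.0, kp2=2.0, k=1.0, beta1=1.0, gamma1=1.0)


@pytest.fixture
def unit_config() -> CircuitConfig:
    return CircuitConfig(TrMG_tot=100.0, TiMG_tot=100.0)


@pytest.fixture
def step_schedule() -> InputSchedule:
    return InputSchedule(((0.0, "A", 20.0),))


@pytest.fixture
def clean_mm() -> MeasurementModel:
    return MeasurementModel(noise_sd=0.0, bleach_amp=0.0, seed=0)


@pytest.fixture
def fig4_conditions(config):
    """Enzyme and template-ratio variations around the reference mix."""
    conds = []
    for rnap in (86.0, 171.0, 342.0):
        conds.append(config.replace(rnap=rnap))
    for rr in (37.5, 75.0, 150.0):
        conds.append(config.replace(rnase_r=rr))
    for ratio in (1 / 3, 1.0, 3.0):
        conds.append(config.replace(TrMG_tot=200 * ratio / (1 + ratio),
                                    TiMG_tot=200 / (1 + ratio)))
    return conds
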