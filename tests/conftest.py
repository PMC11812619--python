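import numpy as np
import pytest

from biovalor import synthetic_data as synth


@pytest.fixture
def no_biochar_params() -> synth.KineticParams:
    """First-order parameters of the reference no-additive condition."""
    return synth.KineticParams("first_order", b0=0.204, k=0.57)


@pytest.fixture
def gompertz_params() -> synth.KineticParams:
    return synth.KineticParams("gompertz", b0=0.204, rm=76.12, lam=0.0)


@pytest.fixture
def daily_schedule() -> synth.MeasurementSchedule:
    return synth.MeasurementSchedule(gas_volume_days=tuple(range(0, 26)))


@pytest.fixture
def noiseless_bottle() -> synth.BottleSpec:
    return synth.BottleSpec("no_biochar", n_replicates=2, vs_feedstock=1.0, noise_sd=0.0, seed=7)


@pytest.fixture
def noiseless_dataset(no_biochar_params, noiseless_bottle, daily_schedule):
    blank_spec = synth.BottleSpec("blank", n_replicates=2, vs_feedstock=0.0, noise_sd=0.0, seed=11)
    return synth.gen_bmp_experiment(
        {"no_biochar": (no_biochar_params, noiseless_bottle)}, blank_spec, daily_schedule
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260905)
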