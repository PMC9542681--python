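import numpy as np
import pytest

import floralsym as fs


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture
def fall_pairing():
    return fs.default_pairing("fall")


@pytest.fixture
def fall_template():
    return fs.default_template("fall")


@pytest.fixture
def small_fall_dataset():
    """15 flowers, falls only, study-condition defaults, fixed seed."""
    params = fs.SimulationParams.defaults(
        n_flowers=15, seed=99, organ_types=("fall",)
    )
    records, configs = fs.generate_dataset(params)
    organs = fs.organs_table(records, configs)
    return params, records, configs, organs


def simulate_falls(
    n_flowers,
    seed,
    compass_amplitude=0.0,
    relative_amplitude=0.0,
    organ_da_amplitude=0.0,
    **kwargs,
):
    """Falls-only dataset with chosen injected effects; returns organs table too."""
    params = fs.SimulationParams.defaults(
        n_flowers=n_flowers,
        seed=seed,
        organ_types=("fall",),
        compass_amplitude=compass_amplitude,
        relative_amplitude=relative_amplitude,
        organ_da_amplitude=organ_da_amplitude,
        **kwargs,
    )
    records, configs = fs.generate_dataset(params)
    organs = fs.organs_table(records, configs)
    return params, records, configs, organs
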