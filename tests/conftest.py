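import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import odoradapt as oa

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def protocol() -> oa.StimulusProtocol:
    """Fast two-block design: 10 trials, 1-s window, 50-ms bins."""
    return oa.StimulusProtocol(
        n_trials_per_block=10,
        odor_window_s=(0.0, 1.0),
        block_sequence=["hex_H", "hex_L"],
    )


@pytest.fixture(scope="session")
def full_protocol() -> oa.StimulusProtocol:
    """The reference 25-trial, 4-s, 50-ms-bin block design."""
    return oa.default_block_protocol(("hex_H", "hex_L", "oct_H", "oct_L"))


@pytest.fixture(scope="session")
def model(protocol) -> oa.PopulationModel:
    return oa.make_population_model(
        odors=("hex",), protocol=protocol, n_units=20, seed=42
    )


@pytest.fixture(scope="session")
def events(model, protocol) -> pd.DataFrame:
    return oa.simulate_session(model, protocol, seed=42)


@pytest.fixture(scope="session")
def tensor(events, model, protocol) -> oa.TrialTensor:
    return oa.bin_spikes(events, protocol, unit_labels=model.unit_labels())


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def make_rank3_tensor(rng, shape=(12, 10, 8), noise_sd_frac=0.0):
    """Random rank-3 tensor (plus optional Gaussian noise) and its factors."""
    a = rng.standard_normal((shape[0], 3))
    b = rng.standard_normal((shape[1], 3))
    c = rng.standard_normal((shape[2], 3))
    x = np.einsum("if,jf,kf->ijk", a, b, c)
    if noise_sd_frac:
        x = x + rng.standard_normal(x.shape) * noise_sd_frac * x.std()
    return x, (a, b, c)
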