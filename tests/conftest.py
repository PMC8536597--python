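import warnings

import numpy as np
import pytest

from thermomca.model_core import load_default_network
from thermomca.synthetic_data import (
    build_default_kinetic_model,
    generate_perturbation_dataset,
)


@pytest.fixture(scope="session")
def default_net():
    return load_default_network()


@pytest.fixture(scope="session")
def trp_toy():
    return build_default_kinetic_model("trp_toy", seed=1)


@pytest.fixture(scope="session")
def toy_dataset_clean(trp_toy):
    """Noise-free 13-state dataset on the trp_toy preset."""
    return generate_perturbation_dataset(trp_toy, noise_cv=0.0, seed=1)


@pytest.fixture(scope="session")
def toy_dataset_noisy(trp_toy):
    return generate_perturbation_dataset(trp_toy, noise_cv=0.1, seed=1)


@pytest.fixture(autouse=True)
def _quiet_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


def classification_from_model(model, threshold=10.0):
    """Near/far labels from a kinetic model's reference reaction energies."""
    return {
        rid: ("near" if abs(g) < threshold else "far")
        for rid, g in model.drg_ref.items()
    }


def internal_E_and_N(model, E_full=None):
    """Restrict an elasticity matrix and N to the balanced metabolites."""
    from thermomca.model_core import stoichiometric_matrix

    net = model.network
    idx = model.balanced_idx
    N_int = stoichiometric_matrix(net)[idx]
    E = model.elasticities if E_full is None else E_full
    E_int = E[:, idx].copy()
    for rid in model.supply_rates:
        E_int[net.rxn_idx(rid)] = 0.0
    return E_int, N_int
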