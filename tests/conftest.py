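import numpy as np
import pandas as pd
import pytest

from fecalmethods import generate_manifest
from fecalmethods.simulate import SimulationParams, simulate_metabolome, simulate_microbiome
from fecalmethods.tables import AbundanceTable


@pytest.fixture(scope="session")
def manifest8():
    """The default eight-subject, six-method crossed design."""
    return generate_manifest(8)


@pytest.fixture(scope="session")
def species_table(manifest8):
    params = SimulationParams(n_features=60, seed=11)
    return simulate_microbiome(manifest8, params, level="SPECIES")


@pytest.fixture(scope="session")
def metabolite_matrix(manifest8):
    params = SimulationParams(
        n_features=120,
        mu_mean=float(np.log(1e4)),
        mu_sd=1.5,
        lod=400.0,
        n_qc=6,
        adduct_dup_frac=0.15,
        seed=12,
    )
    return simulate_metabolome(manifest8, params)


@pytest.fixture()
def tiny_table():
    """Four samples, hand-sized compositions."""
    data = pd.DataFrame(
        {
            "s1": [0.5, 0.25, 0.25, 0.0],
            "s2": [0.25, 0.25, 0.25, 0.25],
            "s3": [1.0, 0.0, 0.0, 0.0],
            "s4": [0.0, 0.5, 0.5, 0.0],
        },
        index=["fA", "fB", "fC", "fD"],
    )
    return AbundanceTable(data, level="SPECIES")
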