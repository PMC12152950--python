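import numpy as np
import pytest

from alfe import chemlib, synth, ti


@pytest.fixture(scope="session")
def gl9():
    return ti.gauss_legendre_schedule(9)


@pytest.fixture(scope="session")
def toy_library():
    """Ten hand-picked molecules spanning oxamides, rings, and acyclics."""
    smiles = {
        "benzene": "c1ccccc1",
        "cyclohexane": "C1CCCCC1",
        "toluene": "Cc1ccccc1",
        "butane": "CCCC",
        "oxamide": "NC(=O)C(=O)N",
        "n-methyl-oxamide": "CNC(=O)C(=O)N",
        "phenyl-oxamide": "O=C(N)C(=O)Nc1ccccc1",
        "pyridine": "c1ccncc1",
        "ethylbenzene": "CCc1ccccc1",
        "acetamide": "CC(N)=O",
    }
    return [chemlib.MoleculeRecord.from_smiles(k, v) for k, v in smiles.items()]


@pytest.fixture(scope="session")
def small_analog_library():
    return synth.default_library(n_max=60, seed=7)


@pytest.fixture(scope="session")
def oracle_spec():
    return synth.default_oracle_spec(seed=7)


def ar1_series(rng: np.random.Generator, n: int, tau: float, sd: float = 1.0,
               mean: float = 0.0) -> np.ndarray:
    phi = np.exp(-1.0 / tau)
    innov = rng.normal(0.0, sd * np.sqrt(1 - phi**2), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i]
    return mean + x
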