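import numpy as np
import pandas as pd
import pytest

from herdlife.pedigree import PedigreeTable
from herdlife.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def trio_pedigree():
    """Two unrelated founders and one progeny."""
    return PedigreeTable.from_frame(
        pd.DataFrame({"animal": [1, 2, 3], "sire": [0, 0, 1], "dam": [0, 0, 2]})
    )


@pytest.fixture(scope="session")
def fullsib_mating_pedigree():
    """Full sibs 3, 4 mated to produce 5 (F = 0.25)."""
    return PedigreeTable.from_frame(
        pd.DataFrame(
            {"animal": [1, 2, 3, 4, 5], "sire": [0, 0, 1, 1, 3], "dam": [0, 0, 2, 2, 4]}
        )
    )


def random_pedigree(n: int, n_founders: int, seed: int, unknown_rate: float = 0.0) -> PedigreeTable:
    rng = np.random.default_rng(seed)
    sire = [0] * n_founders
    dam = [0] * n_founders
    for i in range(n_founders, n):
        s = int(rng.integers(1, i + 1)) if rng.random() >= unknown_rate else 0
        d = int(rng.integers(1, i + 1))
        sire.append(s)
        dam.append(d)
    return PedigreeTable.from_frame(
        pd.DataFrame({"animal": range(1, n + 1), "sire": sire, "dam": dam})
    )


@pytest.fixture(scope="session")
def binary_dataset():
    """Mid-sized binary survival dataset with raw records and censoring."""
    cfg = SimulationConfig(
        n_founders=100, n_generations=2, dams_per_sire=4, progeny_per_dam=3, seed=7
    )
    return cfg, simulate_dataset(cfg)
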