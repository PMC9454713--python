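import numpy as np
import pandas as pd
import pytest

from sgeblup.pedigree import validate_and_sort
from sgeblup.simulate import SimConfig, simulate_all


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One small two-population simulation shared across read-only tests."""
    cfg = SimConfig(
        seed=11,
        n_founders_per_breed={"DUC": 30, "KNP": 12},
        n_litters_per_gen={"DUC": 8, "CROSS": 8},
        litter_size_mean=6.0,
        n_snps=300,
        n_chromosomes=3,
    )
    ped, gset, pheno, truth = simulate_all(cfg)
    return {"config": cfg, "ped": ped, "gset": gset, "pheno": pheno, "truth": truth}


def make_pedigree(rows, cols=("id", "sire", "dam")):
    return validate_and_sort(pd.DataFrame(rows, columns=list(cols)))
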