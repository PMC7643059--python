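import numpy as np
import pandas as pd
import pytest

import tdrive as td


@pytest.fixture(scope="session")
def study_sim():
    """A large simulated dataset under the study's point estimates:
    behavioural polyandry P = 0.609, drive strength d = 0.9,
    competitiveness c = 0.113, carrier frequency near the observed ~12%,
    >= 5000 litters."""
    cfg = td.SimConfig(
        n_founders=400,
        n_t_founders=48,
        n_generations=4,
        n_adults=1300,
        P=0.609,
        d=0.9,
        c=0.113,
        seed=1,
        n_litters=6000,
    )
    return td.simulate(cfg)


@pytest.fixture(scope="session")
def small_sim():
    """A quick default-parameter run for structural checks."""
    cfg = td.SimConfig(n_founders=60, n_t_founders=16, n_generations=3, n_adults=120, seed=7)
    return td.simulate(cfg)


def make_litters(litter_specs):
    """Construct a litters table from (litter_id, mother_id, mother_genotype,
    [(pup_genotype, sire_id), ...]) tuples."""
    rows = []
    pup = 0
    for litter_id, mother_id, mother_geno, pups in litter_specs:
        for geno, sire in pups:
            pup += 1
            rows.append(
                {
                    "litter_id": litter_id,
                    "mother_id": mother_id,
                    "mother_genotype": mother_geno,
                    "cohort": 1,
                    "pup_id": f"P{pup:04d}",
                    "pup_genotype": geno,
                    "sire_id": sire,
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture
def litters_factory():
    return make_litters
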