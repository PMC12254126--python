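import numpy as np
import pandas as pd
import pytest

from mrsurv import SimulationParams, apply_exclusions, compute_score, simulate_cohort

PCS = ("pc1", "pc2", "pc3", "pc4")


@pytest.fixture(scope="session")
def small_params():
    return SimulationParams(n_individuals=8000, n_variants_bmi=80,
                            n_variants_diab=60, seed=42)


@pytest.fixture(scope="session")
def small_sim(small_params):
    return simulate_cohort(small_params)


@pytest.fixture(scope="session")
def scored_cohort(small_sim):
    """Post-exclusion 35-74 analysis set with standardized scores."""
    young, old, ledger = apply_exclusions(small_sim.table, small_sim.flags)
    dos = small_sim.geno.dosages.loc[young.index]
    bmi_gs = compute_score(dos, small_sim.panel, "bmi",
                           small_sim.geno.coded_allele,
                           small_sim.geno.other_allele)
    diab_gs = compute_score(dos, small_sim.panel, "diab",
                            small_sim.geno.coded_allele,
                            small_sim.geno.other_allele)
    return young.assign(bmi_score=bmi_gs.std.to_numpy(),
                        diab_score=diab_gs.std.to_numpy())


@pytest.fixture()
def toy_panel():
    return pd.DataFrame({
        "variant_id": ["v1", "v2", "v3"],
        "effect_allele": ["A", "C", "G"],
        "other_allele": ["G", "T", "A"],
        "weight": [0.5, -0.2, 0.1],
        "allele_freq": [0.3, 0.5, 0.8],
        "trait": ["bmi", "bmi", "bmi"],
    })


@pytest.fixture()
def toy_dosages():
    rng = np.random.default_rng(1)
    return pd.DataFrame(rng.integers(0, 3, size=(40, 3)).astype(float),
                        columns=["v1", "v2", "v3"])
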