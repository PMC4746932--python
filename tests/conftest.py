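import numpy as np
import pytest

import gdttc


@pytest.fixture(scope="session")
def family_kinship():
    """30-donor kinship with 6 families of 5 — non-flat spectrum."""
    gt = gdttc.simulate_genotypes(30, 400, n_families=6, seed=42)
    return gdttc.compute_kinship(gt)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort with one planted module (seeded)."""
    cfg = gdttc.SimulationConfig(
        n_donors=120,
        n_snps=300,
        genes_per_tissue=60,
        module_size=15,
        signal_strength=0.5,
        donor_overlap_fraction=0.8,
        n_families=24,
        seed=7,
    )
    return gdttc.simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
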