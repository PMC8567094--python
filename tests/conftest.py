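import numpy as np
import pandas as pd
import pytest

import triadqtl as tq


@pytest.fixture(scope="session")
def small_config():
    base = dict(seed=0, n_f2=200, n_chrom=2, n_snps_per_chrom=100, n_transcripts=60)
    g0 = tq.simulate_genotypes(tq.SimConfig(**base))
    cis_snp = [s for s in tq.informative_snps(g0) if s.startswith("snp_c1_")][25]
    return tq.SimConfig(
        **base,
        planted_cis=[("tx00040", cis_snp, 0.3)],
        module_spec=[(25, 0.4)],
        trait_spec=[
            tq.TraitSpec(name="trait_med", mediators=[("tx00040", 0.2)], h2=0.3),
            tq.TraitSpec(name="trait_null"),
        ],
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """One desk-scale simulated cross shared across structural tests."""
    return tq.simulate_dataset(small_config)


@pytest.fixture(scope="session")
def small_f2(small_dataset):
    genotypes, _, _, _ = small_dataset
    return genotypes.subset(samples=genotypes.f2_samples())


@pytest.fixture(scope="session")
def small_kinship(small_f2):
    return tq.compute_grm(small_f2)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
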