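import numpy as np
import pandas as pd
import pytest

from inducergp.genotypes import GenotypeMatrix
from inducergp.simulate import SimConfig, default_config, simulate_study


def marker_frame(m, chrom="1", start=1):
    return pd.DataFrame(
        {"id": [f"M{j}" for j in range(m)], "chrom": [chrom] * m,
         "pos": np.arange(start, start + m)}
    )


def random_genotypes(n, m, seed=0, het_rate=0.0):
    """Unstructured {-1, 1} (optionally with heterozygotes) genotype matrix."""
    rng = np.random.default_rng(seed)
    codes = rng.choice([-1.0, 1.0], size=(n, m))
    if het_rate:
        codes[rng.random((n, m)) < het_rate] = 0.0
    return GenotypeMatrix([f"L{i}" for i in range(n)], marker_frame(m), codes)


@pytest.fixture(scope="session")
def small_study():
    """A light multi-family study (23 families, ~1200 SNPs) for pipeline
    tests that do not need the full marker density."""
    cfg = default_config(1)
    cfg.snps_per_chrom = 120
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def dh_family_50x500():
    """A 50-line DH family segregating at all 500 SNPs (parents fixed for
    opposite alleles), the structured fixture for the GBLUP oracle."""
    from inducergp.simulate import SimConfig, simulate_dh_family, simulate_founders

    cfg = SimConfig(n_founders=2, n_chrom=5, snps_per_chrom=100,
                    chrom_length_cM=120, seed=3)
    founders = simulate_founders(cfg)
    parentA = np.ones(founders.n_markers)
    parentB = -np.ones(founders.n_markers)
    return simulate_dh_family(parentA, parentB, 50, founders.markers, seed=11)
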