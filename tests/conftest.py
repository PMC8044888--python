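import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from polymr import simulate as sim

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params_small() -> sim.SimParams:
    return sim.SimParams(n_individuals=500, n_variants=40, n_causal=20, seed=11)


@pytest.fixture(scope="session")
def genotypes_small(params_small):
    return sim.generate_genotypes(params_small)


@pytest.fixture(scope="session")
def weights_small(params_small, genotypes_small):
    table, true = sim.generate_weights(genotypes_small, params_small)
    return table, true


@pytest.fixture(scope="session")
def cohort_small(params_small, genotypes_small, weights_small):
    _, true = weights_small
    return sim.generate_cohort(genotypes_small, true, params_small)


def tiny_genotypes(dosages, chrom=None, pos=None, a1=None, a2=None):
    """Hand-built GenotypeMatrix for targeted unit tests."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    variants = pd.DataFrame(
        {
            "snp": [f"v{j}" for j in range(m)],
            "chr": chrom if chrom is not None else [1] * m,
            "bp": pos if pos is not None else list(range(100, 100 + m)),
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
            "freq": [0.3] * m,
        }
    )
    return sim.GenotypeMatrix(dosages, variants, pd.Index([f"i{k}" for k in range(n)]))


def tiny_weights(betas, pvals=None, snps=None, chrom=None, pos=None, a1=None, a2=None):
    m = len(betas)
    return pd.DataFrame(
        {
            "snp": snps if snps is not None else [f"v{j}" for j in range(m)],
            "chr": chrom if chrom is not None else [1] * m,
            "bp": pos if pos is not None else list(range(100, 100 + m)),
            "a1": a1 if a1 is not None else ["A"] * m,
            "a2": a2 if a2 is not None else ["G"] * m,
            "beta": list(betas),
            "se": [0.01] * m,
            "p": pvals if pvals is not None else [0.5] * m,
        }
    )
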