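import numpy as np
import pandas as pd
import pytest

from fritassoc.data import GenotypeMatrix
from fritassoc.simulate import SnpEffect, study_dataset


def make_geno(calls: dict[str, list[str]], samples: list[str]) -> GenotypeMatrix:
    return GenotypeMatrix(pd.DataFrame(calls, index=samples))


def make_meta(samples, populations, environments=None, sexes=None, families=None):
    n = len(samples)
    env_of = environments or {}
    return pd.DataFrame(
        {
            "population": populations,
            "environment": [env_of.get(p, "fragmented") for p in populations],
            "sex": sexes if sexes is not None else ["male"] * n,
            "family": families if families is not None else list(samples),
            "year": ["2010"] * n,
        },
        index=pd.Index(samples),
    )


@pytest.fixture(scope="session")
def study_ds():
    """Study-scale fixture with a planted dominant causal SNP and one
    environment-divergent locus."""
    return study_dataset(
        11,
        causal=[SnpEffect("snp05", "dominant", 0.8)],
        divergent={"snp40": (0.45, 0.05)},
        maf_override={"snp05": 0.3},
    )


@pytest.fixture(scope="session")
def null_ds():
    """Study-scale fixture with no genetic effects."""
    return study_dataset(12)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
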