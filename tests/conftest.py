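import numpy as np
import pandas as pd
import pytest

from poolburden import fixtures
from poolburden.containers import GenotypeMatrix


@pytest.fixture(scope="session")
def variant_table():
    return fixtures.load_variant_table()


@pytest.fixture(scope="session")
def carrier_counts():
    return fixtures.load_carrier_counts()


@pytest.fixture(scope="session")
def region_map():
    return fixtures.load_region_map()


@pytest.fixture(scope="session")
def study_matrix():
    """Genotype matrix reconstructing the published per-region carrier counts."""
    return fixtures.build_carrier_genotypes()


@pytest.fixture(scope="session")
def study_regions():
    return fixtures.fixture_region_variants()


def make_matrix(genotype_rows, cohorts, comorbid=None):
    """Small-matrix helper: genotype_rows is a list of per-sample genotype
    lists, one column per variant v0..vK."""
    geno = pd.DataFrame(
        np.asarray(genotype_rows, dtype=np.int8),
        index=pd.Index([f"s{i}" for i in range(len(genotype_rows))], name="sample_id"),
        columns=[f"v{j}" for j in range(len(genotype_rows[0]))],
    )
    samples = pd.DataFrame(
        {
            "cohort": cohorts,
            "comorbid": comorbid if comorbid is not None else [False] * len(cohorts),
        },
        index=geno.index,
    )
    return GenotypeMatrix(geno, samples)
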