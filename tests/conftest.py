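import numpy as np
import pandas as pd
import pytest

from fampoly.cohort import PedigreeCohort
from fampoly.simulate import CohortSpec, simulate_cohort


def make_cohort(samples_rows, genotypes, markers=None):
    """Hand-built cohort from (fid, iid, father, mother, sex, pheno) rows."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n_markers = genotypes.shape[1]
    if markers is None:
        markers = pd.DataFrame(
            {
                "snp": [f"m{j}" for j in range(n_markers)],
                "chrom": 1,
                "pos": (np.arange(n_markers) + 1) * 1000,
                "a1": "A",
                "a2": "G",
            }
        )
    samples = pd.DataFrame(
        samples_rows, columns=["fid", "iid", "father", "mother", "sex", "phenotype"]
    )
    return PedigreeCohort(samples=samples, markers=markers, genotypes=genotypes)


@pytest.fixture(scope="session")
def family_cohort():
    """Medium family cohort with LD blocks, no risk loci (null)."""
    spec = CohortSpec(
        n_families=60,
        n_children=2,
        n_unrelated_cases=40,
        n_unrelated_controls=40,
        n_markers=300,
        ld_block_length=10,
        within_block_r=0.8,
        seed=11,
    )
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def founders_cohort():
    """Unrelated founders only, independent markers."""
    spec = CohortSpec(
        n_families=0,
        n_children=0,
        n_unrelated_cases=100,
        n_unrelated_controls=100,
        n_markers=400,
        ld_block_length=1,
        within_block_r=0.0,
        seed=12,
    )
    return simulate_cohort(spec)
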