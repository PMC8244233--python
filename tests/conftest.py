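import pandas as pd
import pytest

from vitdmr.phenotypes import phenotype_cohort
from vitdmr.simulate import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One seeded cohort at the default study size, shared across tests."""
    return generate_cohort(SimulationConfig(seed=20240915))


@pytest.fixture(scope="session")
def phenotyped_cohort(default_cohort) -> pd.DataFrame:
    pheno = phenotype_cohort(default_cohort)
    for col in ("ms_case", "t2d_case", "abnormal_sbp", "abnormal_dbp"):
        pheno[col] = pheno[col].astype(float)
    return pheno
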