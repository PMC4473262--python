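import numpy as np
import pandas as pd
import pytest

from crossomics import preprocess, synth
from crossomics.matrix import OmicsMatrix


@pytest.fixture(scope="session")
def small_config():
    return synth.SynthConfig(
        n_samples=300,
        n_metabolites=12,
        n_transcripts=30,
        n_modules=2,
        module_rho=0.5,
        missing_rate_range=(0.0, 0.2),
        n_snps=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synth.generate_cohort(small_config)


@pytest.fixture(scope="session")
def adjusted(small_cohort):
    """Residual-scale metabolome and transcriptome of the small cohort."""
    met = preprocess.log_and_adjust(small_cohort.metabolome, small_cohort.covariates)
    trans = preprocess.adjust_covariates(small_cohort.transcriptome, small_cohort.covariates)
    return met, trans


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_matrix(values, scale_tag="raw", samples=None, features=None):
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    samples = samples or [f"s{i}" for i in range(n)]
    features = features or [f"f{j}" for j in range(m)]
    return OmicsMatrix(pd.DataFrame(values, index=samples, columns=features), scale_tag=scale_tag)
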