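import numpy as np
import pandas as pd
import pytest

from bioaccel import KDMBioAge, SynthConfig, generate_cohort, generate_reference


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(n_reference=4000, n_cohort=8000, seed=7)


@pytest.fixture(scope="session")
def reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def kdm_fitted(reference):
    return KDMBioAge().fit(reference)


@pytest.fixture(scope="session")
def cohort(small_config, kdm_fitted):
    rng = np.random.default_rng(small_config.seed)
    generate_reference(small_config, rng)  # advance the stream as the pipeline does
    return generate_cohort(small_config, kdm_fitted.params_, rng=rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def random_phenoage_panels():
    """100 random but physiologic panels for formula-transcription oracles."""
    r = np.random.default_rng(42)
    n = 100
    return pd.DataFrame({
        "albumin": r.uniform(35, 52, n),
        "creatinine": r.uniform(45, 120, n),
        "glucose": r.uniform(3.8, 9.0, n),
        "crp": r.uniform(0.02, 2.0, n),
        "lymphocyte_pct": r.uniform(12, 45, n),
        "mcv": r.uniform(75, 100, n),
        "rdw": r.uniform(11.5, 16.5, n),
        "alkaline_phosphatase": r.uniform(40, 140, n),
        "wbc": r.uniform(3.0, 11.0, n),
        "age": r.uniform(40, 69, n),
    })
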