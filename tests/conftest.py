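import numpy as np
import pandas as pd
import pytest

from methar.synthdata import CohortConfig, generate_cohort


def small_config(seed: int = 0, **overrides) -> CohortConfig:
    """A scaled-down cohort used by most tests: 2,000 probes, 400 genes."""
    defaults = dict(
        n_probes=2000, n_genes=400, n_t_hyper=40, n_m_hypo=30,
        n_ar_corr=60, seed=seed,
    )
    defaults.update(overrides)
    return CohortConfig(**defaults)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(small_config(seed=11))


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size cohort shared by the slower end-to-end checks."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_beta_matrix(rng, n_probes=50, n_samples=10, prefix="cg"):
    values = rng.uniform(0.02, 0.98, size=(n_probes, n_samples))
    return pd.DataFrame(
        values,
        index=[f"{prefix}{i:05d}" for i in range(n_probes)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )
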