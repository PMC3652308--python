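import numpy as np
import pandas as pd
import pytest

from leukosplice import synthetic_data as sd


@pytest.fixture(scope="session")
def small_reference():
    return sd.generate_mirna_reference(n_mirnas=20, n_star=4, seed=7, n_shared=2)


@pytest.fixture(scope="session")
def base_design():
    return sd.StudyDesign(libraries_per_condition=3, planted_de={}, seed=11)


@pytest.fixture(scope="session")
def clean_readset(small_reference, base_design):
    """Reads without isomiR/mismatch noise (exact recovery regime)."""
    return sd.simulate_reads(
        small_reference, base_design, mean_depth=800, p_iso=0.0, p_mm=0.0,
        phi=0.1, seed=11,
    )


def nb_counts(rng, mu, phi, shape):
    """Independent NB draws with mean mu and dispersion phi."""
    mu = np.broadcast_to(np.asarray(mu, dtype=float), shape)
    if phi <= 0:
        return rng.poisson(mu)
    return rng.negative_binomial(1.0 / phi, 1.0 / (1.0 + phi * mu))


@pytest.fixture(scope="session")
def two_group_counts():
    """2000 null NB features, mean 200, phi 0.1, 3 + 3 libraries."""
    rng = np.random.default_rng(101)
    y = nb_counts(rng, 200.0, 0.1, (2000, 6))
    cols = [f"s{i}" for i in range(6)]
    df = pd.DataFrame(y, columns=cols)
    groups = pd.Series(["A"] * 3 + ["B"] * 3, index=cols)
    return df, groups
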