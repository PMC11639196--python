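import numpy as np
import pandas as pd
import pytest

from phenosense import (
    attach_covariates,
    filter_observations,
    fit_global,
    generate_climate_grid,
    generate_observations,
)
from phenosense.synthetic import RegionSpec, SensitivityTruth


@pytest.fixture(scope="session")
def default_grid():
    """Full-extent synthetic grid with the default climate gradients."""
    return generate_climate_grid(seed=11)


@pytest.fixture(scope="session")
def small_grid():
    """Compact two-continent grid for fast unit tests."""
    region = RegionSpec(
        lat_range=(45.0, 55.0),
        lon_bands={"North America": (-90.0, -85.0), "Eurasia": (0.0, 5.0)},
    )
    return generate_climate_grid(region, seed=7)


@pytest.fixture(scope="session")
def small_covariates(small_grid):
    """Curated synthetic observations with covariates attached (n=1800)."""
    obs = generate_observations(small_grid, n_per_species_continent=150, seed=13)
    kept, _ = filter_observations(obs)
    return attach_covariates(kept, small_grid)


@pytest.fixture(scope="session")
def global_fit(small_covariates):
    """Global interaction model fitted on the small synthetic dataset."""
    return fit_global(small_covariates)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240521)


def random_linear_dataset(rng, n=60, n_factors=1, n_covariates=2):
    """Small random dataset with categorical and numeric columns."""
    data = {}
    factor_names = []
    for i in range(n_factors):
        k = int(rng.integers(2, 4))
        name = f"f{i}"
        data[name] = rng.choice([f"{name}_l{j}" for j in range(k)], n)
        factor_names.append(name)
    cov_names = [f"x{i}" for i in range(n_covariates)]
    for name in cov_names:
        data[name] = rng.normal(0, 1, n)
    df = pd.DataFrame(data)
    df["y"] = rng.normal(0, 1, n)
    for name in cov_names:
        df["y"] += rng.normal(0, 1) * df[name]
    return df, factor_names, cov_names
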