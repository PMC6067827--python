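import numpy as np
import pytest

from normsig.expr_io import ExpressionMatrix, FactorTable, median_center
from normsig.normalization import log_transform
from normsig.synthetic import SyntheticSpec, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_matrix(rng):
    """Random 50x10 raw-intensity matrix."""
    values = np.exp(rng.normal(7, 1.5, size=(50, 10)))
    return ExpressionMatrix(
        values,
        tuple(f"G{i}" for i in range(50)),
        tuple(f"S{j}" for j in range(10)),
        "raw",
    )


@pytest.fixture
def two_group_factors():
    """10 samples, balanced two-level class factor."""
    sids = tuple(f"S{j}" for j in range(10))
    return FactorTable(
        sids, {"class": ("a",) * 5 + ("b",) * 5}, "class"
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (raw matrix, factors, truth)."""
    return generate_dataset(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def default_logged(default_cohort):
    """Log-converted, per-sample median-centered matrix of the default cohort."""
    raw, factors, truth = default_cohort
    return median_center(log_transform(raw)), factors, truth


def pure_null_spec(seed: int, n_genes: int = 2000) -> SyntheticSpec:
    """No class effect, no heterogeneity of any kind, no covariates."""
    return SyntheticSpec(
        seed=seed,
        n_genes=n_genes,
        class_effect=0.0,
        confounder_strength=0.0,
        minor_strength=0.0,
        n_minor_components=0,
        artifact_rate=0.0,
        scale_sd=0.0,
        covariates=(),
    )
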