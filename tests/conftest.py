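import numpy as np
import pytest

from cism24 import _reference as ref
from cism24.coda import close, pivot_basis
from cism24.regression import fit_from_pivot_table
from cism24.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def published_baseline():
    """Geometric-mean day of the published cohort, canonical part order."""
    return close(ref.GEOMETRIC_MEAN_MINUTES)


@pytest.fixture(scope="session")
def published_fit():
    """Fit reconstructed from the published per-component pivot table."""
    return fit_from_pivot_table(ref.PIVOT_COEFFICIENTS)


@pytest.fixture(scope="session")
def canonical_basis():
    return pivot_basis(ref.PARTS)


@pytest.fixture(scope="session")
def small_cohort():
    """A 600-subject synthetic cohort with default demographics."""
    return generate_cohort(default_config(n=600, seed=20260928))


def random_compositions(rng, n, d=5, total=1440.0):
    """Strictly positive rows closed to the day total (log-normal parts)."""
    raw = np.exp(rng.normal(0.0, 1.0, size=(n, d)))
    return raw * (total / raw.sum(axis=1, keepdims=True))
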