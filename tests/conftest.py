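import numpy as np
import pytest

from trclust import (
    Cohort,
    MixtureComponent,
    MixtureModel,
    RatingSeries,
    SyntheticSpec,
    generate_cohort,
    regularize_cohort,
)
from trclust.synthetic import separated_spec


def make_series(pid, weeks, raw, regularize=True):
    from trclust.prep import regularize_grid

    s = RatingSeries(pid, np.asarray(weeks), np.asarray(raw, dtype=float))
    return regularize_grid(s) if regularize else s


@pytest.fixture
def toy_cohort():
    """Five short, fully observed trajectories (regularized)."""
    data = [
        ("a", [0, 1, 2, 3], [24, 20, 15, 11]),
        ("b", [0, 1, 2, 3, 4], [30, 28, 27, 26, 24]),
        ("c", [0, 1, 2], [18, 14, 9]),
        ("d", [0, 1, 2, 3, 4, 5], [22, 21, 22, 20, 19, 19]),
        ("e", [0, 1, 2, 3], [27, 22, 16, 12]),
    ]
    return Cohort([make_series(p, w, r) for p, w, r in data], "MARS")


@pytest.fixture
def toy_model():
    return MixtureModel([
        MixtureComponent(intercept=3.2, slope=-0.20, residual_sd=0.15, weight=0.4),
        MixtureComponent(intercept=3.3, slope=-0.03, residual_sd=0.20, weight=0.6),
    ])


@pytest.fixture(scope="session")
def separated_cohort_7():
    """Regularized 800-patient cohort from 7 well-separated classes."""
    spec = separated_spec(7, n_patients=800)
    cohort, labels = generate_cohort(spec, seed=42)
    return regularize_cohort(cohort), labels, spec


@pytest.fixture(scope="session")
def default_cohort():
    """Default-condition cohort (n=1000, 7 classes, 7.1% missingness)."""
    spec = SyntheticSpec(n_patients=1000, seed=7)
    cohort, labels = generate_cohort(spec, seed=7)
    return regularize_cohort(cohort), labels, spec
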