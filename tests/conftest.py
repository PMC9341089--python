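import numpy as np
import pytest

from ckdval.models import DerivedPredictors, age_band, builtin_models, builtin_score_tables

ALL_FLAGS = ("anemia", "hypertension", "diabetes", "ihd_or_stroke",
             "heart_failure", "ihd", "pvd", "proteinuria", "kidney_stones")


def make_derived(age, female=False, **on) -> DerivedPredictors:
    """DerivedPredictors with every flag defaulting to False."""
    flags = {f: False for f in ALL_FLAGS}
    flags.update(on)
    return DerivedPredictors(age=age, age_band=age_band(age), female=female,
                             **flags)


@pytest.fixture(scope="session")
def registry():
    return builtin_models()


@pytest.fixture(scope="session")
def score_tables():
    return builtin_score_tables()


@pytest.fixture(scope="session")
def small_cohort():
    """One shared synthetic cohort for pipeline-level tests."""
    from ckdval.cohort import CohortConfig, generate
    return generate(CohortConfig(n=3000, seed=42))


def random_instance(rng, n_max=500, n_min=10):
    """Random (pred, y) instance guaranteed to contain both classes."""
    n = int(rng.integers(n_min, n_max + 1))
    pred = rng.random(n)
    y = (rng.random(n) < np.clip(pred + rng.normal(0, 0.3, n), 0.05, 0.95))
    if y.all():
        y[rng.integers(n)] = False
    if not y.any():
        y[rng.integers(n)] = True
    return pred, y.astype(int)
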