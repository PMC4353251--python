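import numpy as np
import pytest

from pbci import synthgen


@pytest.fixture(scope="session")
def profiles():
    return synthgen.default_workload_profiles()


@pytest.fixture(scope="session")
def short_trial(profiles):
    """One 120 s low-workload trial at the identity perturbation."""
    low, _ = profiles
    return synthgen.generate_trial(low, 120, seed=11)


@pytest.fixture(scope="session")
def annotated_session(profiles):
    """Two annotated 120 s trials (low then high)."""
    low, high = profiles
    return synthgen.generate_session(low, high, ("low", "high"), 120, seed=21)


@pytest.fixture(scope="session")
def separable_xy():
    """Linearly separable 2-cluster toy problem, centers +-3 sd, n=200."""
    rng = np.random.default_rng(42)
    n = 100
    x = np.vstack(
        [rng.normal(-3.0, 1.0, size=(n, 4)), rng.normal(3.0, 1.0, size=(n, 4))]
    )
    y = np.concatenate([np.zeros(n, dtype=int), np.ones(n, dtype=int)])
    perm = rng.permutation(2 * n)
    return x[perm], y[perm]
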