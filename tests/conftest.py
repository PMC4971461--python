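import numpy as np
import pytest

import neckstrain as ns
from neckstrain.pipeline import build_matrices


@pytest.fixture(scope="session")
def small_cohort_matrix():
    """18 x 800 trapezius matrix from a default seeded synthetic cohort."""
    spec = ns.CohortSpec(seed=11)
    seqs, _ = ns.generate_cohort(spec)
    mats = build_matrices(seqs, spec.muscles, 800)
    return mats["trapezius"]


@pytest.fixture()
def seeded_xy():
    """Small random regression problem with a planted y-correlated signal."""
    rng = np.random.default_rng(42)
    n, p = 6, 4
    y = np.array([0.0, 0, 0, 1, 1, 1])
    X = rng.normal(size=(n, p)) + np.outer(y, rng.normal(size=p))
    return X, y
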