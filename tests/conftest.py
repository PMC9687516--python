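import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20220914)


@pytest.fixture
def checkerboard4():
    return np.array(
        [[1.0, 2, 1, 2], [2, 1, 2, 1], [1, 2, 1, 2], [2, 1, 2, 1]]
    )


@pytest.fixture
def small_cohort():
    """Four phantoms, one per grade, generated once per session."""
    from eotrh_texture import generate_cohort

    return generate_cohort({0: 1, 1: 1, 2: 1, 3: 1}, base_seed=7)


def random_small_matrix(rng, max_side=6, values=(0, 1, 2)):
    rows = int(rng.integers(4, max_side + 1))
    cols = int(rng.integers(4, max_side + 1))
    return rng.choice(values, size=(rows, cols)).astype(float)
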