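import numpy as np
import pytest

import pnet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_expression():
    """3 features x 4 patients with an obvious class-separating first row."""
    values = np.array([
        [10.0, 9.0, 1.0, 2.0],
        [5.0, 5.5, 5.2, 4.8],
        [1.0, 2.0, 1.5, 1.8],
    ])
    return pnet.ExpressionMatrix(["g1", "g2", "g3"], ["P1", "P2", "P3", "P4"], values)


@pytest.fixture
def small_cohort():
    """Separable synthetic cohort small enough for fast end-to-end tests."""
    spec = pnet.SyntheticSpec(n_patients=40, m_features=120, n_differential=10,
                              effect_size=2.5, unlabeled_fraction=0.1, seed=7)
    return pnet.generate_cohort(spec)


def label_vector(ids, codes):
    return pnet.LabelVector(list(ids), np.asarray(codes, dtype=int))
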