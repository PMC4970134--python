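import numpy as np
import pytest

from vennose import Dataset, default_class_means, generate_feature_table


@pytest.fixture
def three_class_data() -> Dataset:
    """Moderately separated 3-class Gaussian mixture (20 per class, 4-D)."""
    return generate_feature_table(20, default_class_means(3, 4, 1.9), 1.0, seed=11)


@pytest.fixture
def separable_data() -> Dataset:
    """Essentially noise-free 3-class mixture (class gap ~10 sigma)."""
    return generate_feature_table(10, default_class_means(3, 4, 10.0), 1.0, seed=7)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
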