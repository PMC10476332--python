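import numpy as np
import pytest

from gaitforge.core import (
    DiscretizedPattern,
    GaitPattern,
    NormalizationSpec,
    discretize,
    normalize_pattern,
)
from gaitforge.synthetic import SyntheticSubject, sample_pattern


@pytest.fixture(scope="session")
def lgw_pattern() -> GaitPattern:
    """Identity-subject level-ground-walking pattern (201 rows, physical)."""
    return sample_pattern("lgw", SyntheticSubject(), rng_seed=0)


@pytest.fixture(scope="session")
def lgw_normalized(lgw_pattern) -> GaitPattern:
    return normalize_pattern(lgw_pattern, NormalizationSpec(), weight=70.0)


@pytest.fixture(scope="session")
def lgw_sketch(lgw_normalized) -> DiscretizedPattern:
    return discretize(lgw_normalized)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
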