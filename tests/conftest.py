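import numpy as np
import pytest

from snoutshape.outline import SemilandmarkSet
from snoutshape.simulate import OutlineGenConfig, generate_study


@pytest.fixture
def rng():
    return np.random.default_rng(20141105)


@pytest.fixture(scope="session")
def small_study():
    """Compact two-guild study reused across pipeline-level tests."""
    return generate_study(
        OutlineGenConfig(n_browser=15, n_grazer=15, n_unknown=6, p=60, seed=7)
    )


def random_shapes(rng, n, p):
    return [SemilandmarkSet(f"s{i}", rng.normal(size=(p, 2))) for i in range(n)]
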