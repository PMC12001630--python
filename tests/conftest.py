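import numpy as np
import pytest

from satdepth import CountMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def small_matrix(rng):
    """Random 60-gene x 8-sample matrix with a long expression tail."""
    means = np.exp(rng.uniform(np.log(0.2), np.log(200.0), size=60))
    counts = rng.poisson(means[:, None], size=(60, 8))
    return CountMatrix(
        gene_ids=[f"g{i:03d}" for i in range(60)],
        sample_ids=[f"s{j}" for j in range(8)],
        counts=counts,
    )
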