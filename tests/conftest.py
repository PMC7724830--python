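import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def cluster_data():
    """Well-separated two-cluster dataset with a known signal set."""
    from plsdabench.synthetic import GeneratorSpec, generate

    return generate(
        GeneratorSpec(model="cluster", n=120, m=30, s=5, sep=0.9, seed=42)
    )
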