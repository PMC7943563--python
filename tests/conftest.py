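import numpy as np
import pandas as pd
import pytest

from nescore import (
    ExpressionMatrix,
    GeneSetCollection,
    GeneSignature,
    SyntheticConfig,
    generate_dataset,
)


@pytest.fixture(scope="session")
def toy_signature() -> GeneSignature:
    """Four genes with perfectly anti-correlated centroids."""
    return GeneSignature(("g1", "g2", "g3", "g4"), [1, 2, 3, 4], [4, 3, 2, 1])


@pytest.fixture(scope="session")
def synthetic():
    """Default-condition synthetic dataset shared across tests."""
    return generate_dataset(SyntheticConfig(seed=1))


@pytest.fixture()
def small_matrix() -> ExpressionMatrix:
    values = pd.DataFrame(
        [[1.0, 6.0], [2.0, 4.0], [3.0, 2.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2"],
    )
    return ExpressionMatrix(values, scale="log2")


@pytest.fixture()
def toy_sets() -> GeneSetCollection:
    return GeneSetCollection({"up": ["gA", "gB"], "down": ["gC"]})
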