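import numpy as np
import pandas as pd
import pytest

from mesreg.harmonize import ExpressionDataset


def make_dataset(rng, genes, samples, batch_id, loc=0.0, scale=1.0):
    vals = rng.normal(loc, scale, size=(len(genes), len(samples)))
    df = pd.DataFrame(vals, index=list(genes), columns=list(samples))
    return ExpressionDataset(df, batch_id=batch_id)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def two_batch_datasets(rng):
    genes = [f"g{i}" for i in range(30)]
    a = make_dataset(rng, genes, [f"a{j}" for j in range(8)], "A")
    b = make_dataset(rng, genes, [f"b{j}" for j in range(10)], "B", loc=5.0, scale=2.0)
    return [a, b]
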