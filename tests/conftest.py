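import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from transcriptoscreen.diffexpr import ExpressionMatrix

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


def make_matrix(values: np.ndarray, n_disease: int, genes=None) -> ExpressionMatrix:
    """Wrap a raw array as an ExpressionMatrix; first n_disease columns diseased."""
    n_genes, n_samples = values.shape
    genes = list(genes) if genes is not None else [f"G{i + 1:06d}" for i in range(n_genes)]
    samples = [f"disease_{i + 1}" for i in range(n_disease)] + [
        f"control_{i + 1}" for i in range(n_samples - n_disease)
    ]
    groups = pd.Series(
        ["disease"] * n_disease + ["control"] * (n_samples - n_disease),
        index=pd.Index(samples, name="sample"),
    )
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples),
        groups=groups,
    )


def random_ranked(rng: np.random.Generator, n: int) -> pd.Series:
    """Ranked list with distinct metrics, descending, deterministic per rng."""
    metric = np.sort(rng.normal(size=n))[::-1]
    genes = [f"G{i + 1:06d}" for i in range(n)]
    return pd.Series(metric, index=pd.Index(genes, name="gene"), name="metric")


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """6-sample, 3-gene matrix with one clear disease-up gene."""
    values = np.array(
        [
            [10.1, 11.0, 10.6, 8.0, 8.4, 8.2],  # disease-up
            [5.0, 5.2, 4.9, 5.1, 5.0, 5.05],  # null
            [2.0, 4.0, 3.1, 2.0, 4.0, 3.2],  # noisy null
        ]
    )
    return make_matrix(values, n_disease=3, genes=["GA", "GB", "GC"])
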