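import numpy as np
import pandas as pd
import pytest

from neuromark.study import ExpressionStudy
from neuromark.synthetic import SimConfig, generate_study


@pytest.fixture(scope="session")
def small_config() -> SimConfig:
    """Fast study configuration used across suites: 400 transcripts, 3 planted modules."""
    return SimConfig(
        n_transcripts=400,
        module_sizes=(45, 40, 35),
        n_samples_cns=12,
        n_samples_blood=26,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def make_study(matrix: np.ndarray, samples: pd.DataFrame | None = None) -> ExpressionStudy:
    """Wrap a bare matrix as an ExpressionStudy with identity-ish gene map."""
    ids = [f"T{i:04d}" for i in range(matrix.shape[0])]
    cols = [f"S{j:02d}" for j in range(matrix.shape[1])]
    gene_map = pd.Series([f"G{i:04d}" for i in range(matrix.shape[0])], index=ids)
    if samples is None:
        samples = pd.DataFrame(index=cols)
    else:
        samples = samples.set_axis(cols)
    return ExpressionStudy(pd.DataFrame(matrix, index=ids, columns=cols), gene_map, samples)
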