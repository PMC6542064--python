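import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from tvgranger.preprocess import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def latent_matrix(data: np.ndarray, genes=None) -> ExpressionMatrix:
    """Wrap a raw (possibly signed) latent panel for VAR fitting in tests."""
    k = data.shape[0]
    genes = genes or [f"g{i:02d}" for i in range(k)]
    return ExpressionMatrix(genes, np.asarray(data, dtype=float))
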