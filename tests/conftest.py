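import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def normal_equations_singular_values(M: np.ndarray) -> np.ndarray:
    """Independent oracle: singular values as square roots of the
    eigenvalues of M^T M (computed with a symmetric eigensolver, not an
    SVD), descending."""
    gram = M.T @ M
    eigvals = np.linalg.eigvalsh(gram)
    return np.sqrt(np.clip(eigvals, 0.0, None))[::-1]
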