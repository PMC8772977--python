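import numpy as np
import pytest
from hypothesis import HealthCheck, settings
from scipy.linalg import hadamard

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def orthogonal_design():
    """8x7 orthogonal +/-1 design with a planted coefficient vector.

    Y = 3 X0 + 2 X1 + 4 X2 + 1 X4 + 0.5 X5 (X3, X6 pure noise carriers with
    zero coefficients).  Because the columns are orthogonal with squared
    norm n, every sacrifice score and subset loss has a closed form, which
    makes the worked splicing trajectory exactly checkable.
    """
    H = hadamard(8).astype(float)
    X = H[:, 1:]
    coef = np.zeros(7)
    coef[[0, 1, 2, 4, 5]] = [3.0, 2.0, 4.0, 1.0, 0.5]
    return X, X @ coef, coef
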