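import numpy as np
import pytest

from dtilink.io_tables import InteractionNetwork, KernelMatrix


def rand_psd_kernel(n, rng, side="drug", prefix=None, extra_rank=3):
    """Random PSD kernel with labeled ids (Gram matrix of a random factor)."""
    prefix = prefix or side[0]
    A = rng.standard_normal((n, n + extra_rank))
    return KernelMatrix([f"{prefix}{i}" for i in range(n)], A @ A.T, side)


def rand_pd_kernel(n, rng, side="drug", prefix=None):
    """Strictly positive-definite kernel (Gram + identity jitter)."""
    K = rand_psd_kernel(n, rng, side, prefix)
    return KernelMatrix(K.object_ids, K.values + 0.5 * np.eye(n), side)


def rand_network(n_d, n_p, rng, p=0.3):
    Y = (rng.random((n_d, n_p)) < p).astype(float)
    # guarantee both classes present
    Y[0, 0] = 1.0
    Y[-1, -1] = 0.0
    return InteractionNetwork(
        [f"d{i}" for i in range(n_d)], [f"p{j}" for j in range(n_p)], Y
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240516)
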