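import numpy as np
import pytest

import gxmap as gx


@pytest.fixture(scope="session")
def small_geometry():
    """One donor, 200 samples on the curved sheet (reused read-only)."""
    return gx.generate_geometry(1, 200, seed=1)[0]


@pytest.fixture(scope="session")
def small_graph(small_geometry):
    return gx.build_knn_graph(small_geometry.pairwise_dist, k=10)


@pytest.fixture(scope="session")
def small_basis(small_graph):
    return gx.compute_mem(small_graph)


@pytest.fixture(scope="session")
def recovery_pooled():
    """Three replicates of: 6 donors x 200 samples, 500 genes, 50 planted
    at |rho| = 0.6, with per-map TP/FP pooled across the replicates."""
    return gx.pooled_recovery_study(seeds=(42, 43, 44))


@pytest.fixture(scope="session")
def recovery_outcome(recovery_pooled):
    """A single recovery replicate (for per-fit invariant checks)."""
    return recovery_pooled[1][0]


@pytest.fixture(scope="session")
def type_one_rates():
    """Rejection rates on spatially autocorrelated null genes, 3 seeds."""
    adjusted, unadjusted = gx.type_one_error_study(seeds=(1, 2, 3))
    return np.asarray(adjusted), np.asarray(unadjusted)
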