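import numpy as np
import pytest

import sympnet as sn

#: short penalty path for tests that re-estimate networks many times
FAST_GGM = sn.GGMConfig(n_lambdas=20)


@pytest.fixture(scope="session")
def chain_model():
    """3-node chain ground truth: partial correlations 1-2 and 2-3 only."""
    Omega = np.eye(3)
    Omega[0, 1] = Omega[1, 0] = -0.35
    Omega[1, 2] = Omega[2, 1] = -0.35
    Pcor = -Omega / np.sqrt(np.outer(np.diag(Omega), np.diag(Omega)))
    np.fill_diagonal(Pcor, 1.0)
    thresholds = np.tile([-1.0, 0.0, 1.0], (3, 1))
    return sn.TrueNetworkModel(p=3, Omega=Omega, Pcor_true=Pcor,
                               thresholds=thresholds, n_levels=4)


@pytest.fixture(scope="session")
def small_wave():
    """One moderately sized wave from a sparse 6-node truth."""
    model = sn.make_true_network(6, edge_prob=0.4, weight_range=(0.25, 0.4), seed=11)
    return model, sn.sample_ordinal_wave(model, 400, seed=12)


def make_network(W, labels=None):
    """Wrap a weight matrix as a GGMNetwork for centrality/similarity tests."""
    W = np.asarray(W, dtype=float)
    return sn.GGMNetwork(W=W, Theta=np.eye(W.shape[0]), lambda_selected=0.0,
                         ebic=0.0, node_labels=labels or [])
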