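"""Shared fixtures: reference networks and small toys.

The session-scoped reference network uses the package's default synthetic
reef strip at the calibrated size (114 nodes, 3904 directed links) with a
fixed seed, standing in for the real node table.
"""

import numpy as np
import pytest

import reefresilience as rr

#: fixed seed of the reference synthetic geometry used across the suite
REFERENCE_NETWORK_SEED = 0


@pytest.fixture(scope="session")
def reef114() -> rr.ReefNetwork:
    """Calibrated-size synthetic reef network (114 nodes, 3904 links)."""
    return rr.ReefNetwork.synthetic(114, rng=REFERENCE_NETWORK_SEED)


@pytest.fixture(scope="session")
def small_net() -> rr.ReefNetwork:
    """A 24-node synthetic network for fast pipeline tests."""
    return rr.ReefNetwork.synthetic(24, rng=3)


@pytest.fixture()
def two_node_net() -> rr.ReefNetwork:
    """Two mutually linked nodes 0.1 units apart (single out-link each)."""
    nodes = rr.NodeSet(np.array([[0.0, 0.0], [0.0, 0.1]]))
    return rr.ReefNetwork.from_nodes(nodes)


@pytest.fixture()
def isolated_pair() -> rr.LinkSet:
    """Two nodes with no links at all (independent logistic patches)."""
    return rr.LinkSet(np.array([], dtype=np.int64), np.array([], dtype=np.int64),
                      np.array([]), n_nodes=2)


def single_patch_links() -> rr.LinkSet:
    """A one-node system with no links (pure logistic dynamics)."""
    return rr.LinkSet(np.array([], dtype=np.int64), np.array([], dtype=np.int64),
                      np.array([]), n_nodes=1)


def logistic_closed_form(t, x0, r):
    """X(t) of dX/dt = r X (1 - X) from X(0) = x0."""
    e = np.exp(r * np.asarray(t, dtype=float))
    return x0 * e / (1.0 + x0 * (e - 1.0))


def logistic_crossing_time(x, x0, r):
    """Time at which the logistic reaches level x from x0."""
    return np.log(x * (1.0 - x0) / (x0 * (1.0 - x))) / r
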