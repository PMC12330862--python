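import warnings

import numpy as np
import pytest

import eigenstrap as es

warnings.filterwarnings("ignore", message=".*trailing modes.*")


@pytest.fixture(scope="session")
def sphere3():
    """642-vertex unit icosphere (closed surface workhorse)."""
    return es.make_icosphere(3, 1.0)


@pytest.fixture(scope="session")
def sphere3_r28():
    """Benchmark-scale sphere: 642 vertices, radius 28 mm inside a 64 mm grid."""
    return es.make_icosphere(3, 28.0)


@pytest.fixture(scope="session")
def sphere1():
    """42-vertex icosphere for dense-oracle comparisons."""
    return es.make_icosphere(1, 1.0)


@pytest.fixture(scope="session")
def basis3(sphere3):
    # complete basis: reconstruction is exact
    return es.eigenbasis_for_mesh(sphere3, sphere3.n_vertices)


@pytest.fixture(scope="session")
def basis3_r28(sphere3_r28):
    return es.eigenbasis_for_mesh(sphere3_r28, sphere3_r28.n_vertices - 1)


@pytest.fixture(scope="session")
def dist3(sphere3):
    return es.pairwise_distances(sphere3, metric="geodesic", seed=1)


@pytest.fixture(scope="session")
def dist3_r28(sphere3_r28):
    return es.pairwise_distances(sphere3_r28, metric="geodesic", seed=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
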