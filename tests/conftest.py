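import numpy as np
import pytest

from richconn.core import BinaryGraph, ConnectomeMatrix
from richconn.synthetic import SyntheticSpec, generate_cohort


def make_matrix(weights, subject_id="s0") -> ConnectomeMatrix:
    w = np.asarray(weights, dtype=float)
    ids = [f"n{i}" for i in range(w.shape[0])]
    return ConnectomeMatrix(w, ids, subject_id)


def graph_from_adj(adj, sparsity=0.1) -> BinaryGraph:
    return BinaryGraph(np.asarray(adj), sparsity)


@pytest.fixture(scope="session")
def small_cohort():
    """Compact two-group cohort with a planted rich club (session-cached)."""
    spec = SyntheticSpec(
        n_nodes=40,
        n_per_group={"CN": 12, "MDDSI": 12},
        hub_fraction=0.15,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def aal_cohort():
    """90-node three-group cohort at reduced per-group size (session-cached)."""
    spec = SyntheticSpec(
        n_per_group={"CN": 8, "MDDNSI": 8, "MDDSI": 8}, seed=5
    )
    return generate_cohort(spec)
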