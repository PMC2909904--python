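import networkx as nx
import numpy as np
import pytest

import drugcipher as dc


@pytest.fixture(scope="session")
def toy_probs():
    """4-assignment ATC corpus: N05BA01 ×2, N05BA12 ×1, N02AA01 ×1."""
    assignments = [
        ("d1", "N05BA01"),
        ("d2", "N05BA01"),
        ("d3", "N05BA12"),
        ("d4", "N02AA01"),
    ]
    return dc.estimate_code_probabilities(assignments)


@pytest.fixture(scope="session")
def path_graph():
    """p1 – p2 – p3 path plus an isolated node p4."""
    g = nx.Graph()
    g.add_edges_from([("p1", "p2"), ("p2", "p3")])
    g.add_node("p4")
    return g


@pytest.fixture(scope="session")
def world():
    """Small seeded synthetic world shared across unit tests."""
    return dc.generate_world(n_drugs=30, n_proteins=150, n_modules=6, seed=7)


@pytest.fixture(scope="session")
def world_matrices(world):
    """(ts, cs, phi, distance cache) for the shared world."""
    probs = dc.estimate_code_probabilities(
        [(d.drug_id, c) for d in world.drugs for c in d.atc_codes]
    )
    ts = dc.ts_matrix(world.drugs, probs)
    cs = dc.cs_matrix(world.drugs)
    drug_ids = [d.drug_id for d in world.drugs]
    phi = dc.closeness_matrix(world.graph, world.drugs, drug_ids=drug_ids)
    cache = dc.DistanceCache(world.graph)
    return ts, cs, phi, cache


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
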