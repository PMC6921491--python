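"""Shared fixtures: small random graphs and the desk-scale synthetic study.

The desk-scale fixtures are session-scoped because embedding training is
the expensive step; every test that needs the preset graph, reference DDI
set or trained skip-gram vectors reuses the same instance.
"""

import numpy as np
import pytest

from kgddi.graph_walks import WalkConfig, random_walks
from kgddi.kg_io import Triple, build_graph
from kgddi.embed_models import Word2VecConfig, train_skipgram
from kgddi.synthetic_data import DESK_PRESET, synth_ddis, synth_kg


def random_triples(rng, n_entities=12, n_relations=3, n_triples=30, literal_rate=0.0):
    """Random multigraph triples for property tests."""
    ents = [f"http://x.org/e{i}" for i in range(n_entities)]
    rels = [f"http://x.org/r{i}" for i in range(n_relations)]
    out = []
    for _ in range(n_triples):
        s = ents[rng.integers(n_entities)]
        p = rels[rng.integers(n_relations)]
        if rng.random() < literal_rate:
            out.append(Triple(s, p, f"literal value {rng.integers(100)}", True))
        else:
            out.append(Triple(s, p, ents[rng.integers(n_entities)]))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desk_triples():
    return synth_kg(DESK_PRESET)


@pytest.fixture(scope="session")
def desk_ref(desk_triples):
    return synth_ddis(desk_triples, DESK_PRESET)


@pytest.fixture(scope="session")
def desk_graph(desk_triples):
    return build_graph(desk_triples)


@pytest.fixture(scope="session")
def desk_corpus(desk_graph):
    return random_walks(desk_graph, None, WalkConfig(depth=2, walks_per_entity=100, seed=1))


@pytest.fixture(scope="session")
def desk_embeddings(desk_corpus):
    return train_skipgram(desk_corpus, Word2VecConfig(dim=50, seed=1))
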