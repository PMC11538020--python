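import numpy as np
import pytest

from kgelp.data import KnowledgeGraph


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_kg(rng, n_entities=20, n_relations=3, n_triples=50) -> KnowledgeGraph:
    """Random dense-vocabulary KG (duplicates collapse on construction)."""
    triples = np.column_stack(
        [
            rng.integers(0, n_entities, n_triples),
            rng.integers(0, n_relations, n_triples),
            rng.integers(0, n_entities, n_triples),
        ]
    )
    return KnowledgeGraph(
        [f"e{i}" for i in range(n_entities)],
        [f"r{i}" for i in range(n_relations)],
        triples,
    )


@pytest.fixture
def small_kg(rng):
    return random_kg(rng)
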