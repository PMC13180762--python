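import numpy as np
import pytest

from hypertrail.hypergraph import (ConceptVocabulary, Hyperedge,
                                   TemporalHypergraph)


def make_edge(eid, t, members, source=None):
    return Hyperedge(id=eid, timestamp=t, members=frozenset(members),
                     source_id=source)


def make_hypergraph(edge_specs, n_concepts, year_origin=2000):
    """edge_specs: list of (id, t, members)."""
    vocab = ConceptVocabulary.from_labels(f"c{j}" for j in range(n_concepts))
    T = max(t for _, t, _ in edge_specs) + 1
    snapshots = {t: [] for t in range(T)}
    for eid, t, members in edge_specs:
        snapshots[t].append(make_edge(eid, t, members))
    years = tuple(year_origin + t for t in range(T))
    return TemporalHypergraph(vocabulary=vocab, snapshots=snapshots, years=years)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def chain_hypergraph():
    """One hyperedge per year, consecutive ones overlapping: the unique
    full-length trail is forced."""
    return make_hypergraph(
        [(0, 0, {0, 1}), (1, 1, {1, 2}), (2, 2, {2, 3}), (3, 3, {3, 4})],
        n_concepts=5,
    )


@pytest.fixture
def small_hypergraph():
    return make_hypergraph(
        [
            (0, 0, {0, 1, 2}), (1, 0, {2, 3, 4}),
            (2, 1, {0, 1, 5}), (3, 1, {3, 4, 5}),
            (4, 2, {0, 2, 5}), (5, 2, {1, 3, 4}),
        ],
        n_concepts=6,
    )
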