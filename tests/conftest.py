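"""Shared fixtures: tiny hand-built graphs and random-graph factories."""

from __future__ import annotations

import numpy as np
import pytest

from slkg.graph import EntityTable, HeteroGraph, augment, build_graph, merge_sl_graph


@pytest.fixture
def tiny_kg() -> HeteroGraph:
    """Two genes annotated to one GO term (unaugmented, no SL edges)."""
    entities = EntityTable.from_records(
        [("A", "Gene", "gene A"), ("B", "Gene", "gene B"), ("GO1", "BP", "process 1")]
    )
    rows = [("A", "involved_in", "GO1"), ("B", "involved_in", "GO1")]
    return build_graph(rows, entities)


@pytest.fixture
def chain_graph() -> HeteroGraph:
    """Augmented chain q -> a -> b -> c (plus inverses and identity loops)."""
    entities = EntityTable.from_records(
        [("a", "BP", ""), ("b", "BP", ""), ("c", "Gene", ""), ("q", "Gene", "")]
    )
    rows = [("q", "r1", "a"), ("a", "r2", "b"), ("b", "r3", "c")]
    return augment(build_graph(rows, entities))


@pytest.fixture
def diamond_graph() -> HeteroGraph:
    """Augmented diamond: two parallel 2-hop routes q->x->t and q->y->t."""
    entities = EntityTable.from_records(
        [("q", "Gene", ""), ("x", "BP", ""), ("y", "BP", ""), ("t", "Gene", "")]
    )
    rows = [("q", "r1", "x"), ("q", "r1", "y"), ("x", "r2", "t"), ("y", "r2", "t")]
    return augment(build_graph(rows, entities))


def random_graph(rng: np.random.Generator, n_nodes: int = 20, n_edges: int = 40,
                 n_relations: int = 4, n_sl: int = 3) -> HeteroGraph:
    """Random augmented heterogeneous graph with a few SL pairs."""
    n_genes = max(4, n_nodes // 2)
    records = [(f"g{i:02d}", "Gene", "") for i in range(n_genes)]
    records += [(f"f{i:02d}", "BP", "") for i in range(n_nodes - n_genes)]
    table = EntityTable.from_records(records)
    ids = [r[0] for r in records]
    rows = []
    for _ in range(n_edges):
        h, t = rng.choice(len(ids), size=2, replace=False)
        r = int(rng.integers(n_relations))
        rows.append((ids[h], f"rel{r}", ids[t]))
    kg = build_graph(rows, table)
    pairs = []
    genes = [f"g{i:02d}" for i in range(n_genes)]
    while len(pairs) < n_sl:
        u, v = rng.choice(n_genes, size=2, replace=False)
        pairs.append((genes[u], genes[v]))
    return augment(merge_sl_graph(kg, pairs))


@pytest.fixture
def random_graph_factory():
    return random_graph
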