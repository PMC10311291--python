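"""Layered digraph construction vs the brute-force path-enumeration oracle."""

import numpy as np
import pytest

from slkg.digraph import (
    OracleOverflowError,
    build_union_digraph,
    digraph_to_json,
    enumerate_paths_bruteforce,
    expand_layer,
    slice_pair_digraph,
)
from slkg.graph import EntityTable, GraphError, augment, build_graph


def test_expand_layer_counts(chain_graph):
    g = chain_graph
    q = g.entities.index_of("q")
    src, rel, dst, nxt = expand_layer(g, np.asarray([q]))
    # q has r1 out-edge plus its identity loop (no in-edges to invert)
    assert len(src) == 2
    assert set(nxt.tolist()) == {q, g.entities.index_of("a")}


def test_expand_layer_dedups_shared_neighbor(diamond_graph):
    g = diamond_graph
    x, y, t = (g.entities.index_of(n) for n in ("x", "y", "t"))
    src, rel, dst, nxt = expand_layer(g, np.asarray(sorted([x, y])))
    assert np.sum(nxt == t) == 1  # t appears once in the next frontier


def test_next_frontier_equals_tails(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(0), n_nodes=30, n_edges=60)
    frontier = np.asarray([0, 1, 2])
    src, rel, dst, nxt = expand_layer(g, frontier)
    assert set(nxt.tolist()) == set(dst.tolist())


def test_union_digraph_isolated_source():
    entities = EntityTable.from_records([("q", "Gene", ""), ("z", "Gene", "")])
    g = augment(build_graph([("z", "r", "z")], entities))
    q = g.entities.index_of("q")
    dg = build_union_digraph(g, q, 3)
    for k in range(1, 4):
        assert dg.frontiers[k].tolist() == [q]
        assert dg.layers[k - 1].n_edges == 1  # identity self-loop only


def test_union_digraph_chain_reachability(chain_graph):
    g = chain_graph
    idx = {n: g.entities.index_of(n) for n in "qabc"}
    dg = build_union_digraph(g, idx["q"], 3)
    assert set(dg.frontiers[3].tolist()) >= {idx["q"], idx["a"], idx["b"], idx["c"]}


def test_union_digraph_k_zero_rejected(chain_graph):
    with pytest.raises(GraphError):
        build_union_digraph(chain_graph, 0, 0)


def test_frontier_monotone_under_identity(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(2), n_nodes=25, n_edges=50)
    dg = build_union_digraph(g, 0, 3)
    for k in range(3):
        assert set(dg.frontiers[k].tolist()) <= set(dg.frontiers[k + 1].tolist())


def test_frontier_nodes_distinct(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(9), n_nodes=20, n_edges=40)
    dg = build_union_digraph(g, 1, 3)
    for f in dg.frontiers:
        assert len(f) == len(np.unique(f))


def test_bruteforce_no_walk_empty(chain_graph):
    g = chain_graph
    q, c = g.entities.index_of("q"), g.entities.index_of("c")
    # K=1: c is not adjacent to q
    assert enumerate_paths_bruteforce(g, q, c, 1) == []


def test_bruteforce_chain_unique_path():
    # chain without augmentation: exactly one 3-walk q->a->b->c
    g = build_graph([("q", "r1", "a"), ("a", "r2", "b"), ("b", "r3", "c")])
    q, c = g.entities.index_of("q"), g.entities.index_of("c")
    paths = enumerate_paths_bruteforce(g, q, c, 3)
    assert len(paths) == 1
    assert [p[1] for p in paths[0]] == [
        g.relation_index("r1"), g.relation_index("r2"), g.relation_index("r3")
    ]


def test_bruteforce_diamond_hand_count(diamond_graph):
    g = diamond_graph
    q, t = g.entities.index_of("q"), g.entities.index_of("t")
    # 3-walks q->t: two 2-hop routes padded by identity at either end
    # (id,q)(r1,x|y)(r2,t) and (r1,x|y)(id,.)(r2,t) and (r1,x|y)(r2,t)(id,t)
    # plus routes using inverse edges: q->x->q->y etc. cannot reach t in 3
    # without ending elsewhere; verify by explicit hand count = 6
    paths = enumerate_paths_bruteforce(g, q, t, 3)
    assert len(paths) == 6


def test_bruteforce_budget_guard(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(1), n_nodes=20, n_edges=80)
    with pytest.raises(OracleOverflowError):
        enumerate_paths_bruteforce(g, 0, 1, 3, budget=10)


def test_slice_chain_equals_full_path(chain_graph):
    g = chain_graph
    q, c = g.entities.index_of("q"), g.entities.index_of("c")
    dg = build_union_digraph(g, q, 3)
    sl = slice_pair_digraph(dg, c)
    oracle = enumerate_paths_bruteforce(g, q, c, 3)
    oracle_triples = {t for path in oracle for t in path}
    got = set().union(*(sl.layer_triples(k) for k in range(1, 4)))
    assert got == oracle_triples


def test_slice_excludes_other_endpoint_edges(diamond_graph):
    g = diamond_graph
    q = g.entities.index_of("q")
    dg = build_union_digraph(g, q, 2)
    x = g.entities.index_of("x")
    sl_x = slice_pair_digraph(dg, x)
    # edges exclusive to reaching t at layer 2 must not appear
    t = g.entities.index_of("t")
    layer2 = sl_x.layer_triples(2)
    assert all(d != t for _, _, d in layer2)


def test_slice_idempotent(chain_graph):
    g = chain_graph
    q, c = g.entities.index_of("q"), g.entities.index_of("c")
    dg = build_union_digraph(g, q, 3)
    s1 = slice_pair_digraph(dg, c)
    s2 = slice_pair_digraph(s1, c)
    for k in range(1, 4):
        assert s1.layer_triples(k) == s2.layer_triples(k)


def test_slice_unreachable_rejected(chain_graph):
    g = chain_graph
    q = g.entities.index_of("q")
    dg = build_union_digraph(g, q, 1)
    with pytest.raises(GraphError, match="unreachable"):
        slice_pair_digraph(dg, g.entities.index_of("c"))


def test_slice_matches_oracle_random_graphs(random_graph_factory):
    """Sliced pair digraphs equal the union of brute-force path triples."""
    rng = np.random.default_rng(42)
    for trial in range(10):
        g = random_graph_factory(rng, n_nodes=12, n_edges=18, n_relations=3, n_sl=2)
        dg = build_union_digraph(g, 0, 3)
        for g_p in dg.frontiers[3][:5]:
            paths = enumerate_paths_bruteforce(g, 0, int(g_p), 3)
            oracle_triples = {t for path in paths for t in path}
            sl = slice_pair_digraph(dg, int(g_p))
            got = set().union(*(sl.layer_triples(k) for k in range(1, 4)))
            assert got == oracle_triples


def test_union_equals_union_of_slices(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(7), n_nodes=10, n_edges=14)
    dg = build_union_digraph(g, 0, 3)
    for k in range(1, 4):
        union_k = set()
        for g_p in dg.frontiers[3]:
            union_k |= slice_pair_digraph(dg, int(g_p)).layer_triples(k)
        assert union_k == dg.layer_triples(k)


def test_frontier_k_equals_oracle_endpoints(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(13), n_nodes=12, n_edges=16)
    dg = build_union_digraph(g, 0, 3)
    endpoints = {
        int(e) for e in range(len(g.entities))
        if enumerate_paths_bruteforce(g, 0, e, 3)
    }
    assert endpoints == set(dg.frontiers[3].tolist())


def test_neighbor_sampling_caps_out_degree(random_graph_factory):
    g = random_graph_factory(np.random.default_rng(21), n_nodes=20, n_edges=80)
    rng = np.random.default_rng(0)
    dg = build_union_digraph(g, 0, 3, sample_neighbors=4, rng=rng)
    for layer in dg.layers:
        # per-source non-identity out-degree bounded by the cap
        ident = g.identity_relation
        for s in np.unique(layer.src):
            mask = (layer.src == s) & (layer.rel != ident)
            assert mask.sum() <= 4


def test_digraph_json_roundtrip_fields(chain_graph):
    import json

    g = chain_graph
    dg = build_union_digraph(g, g.entities.index_of("q"), 2)
    obj = json.loads(digraph_to_json(dg))
    assert obj["K"] == 2 and len(obj["layers"]) == 2
    assert obj["source"] == g.entities.index_of("q")
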