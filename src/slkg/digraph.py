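"""Layered relational digraphs rooted at a primary gene.

For a query gene g_q the union of all K-hop relational digraphs is built by
layer-wise frontier expansion (breadth-first style dynamic programming): each
graph edge is touched at most K times, and the per-pair digraph for any
endpoint is recovered afterwards by a backward slice, so no per-pair subgraph
extraction is ever needed.  Identity self-loops inserted at augmentation time
let entities reached in fewer than K hops persist to the last layer, which is
what makes near genes scorable at layer K.

A brute-force K-walk enumerator is provided as an independent test oracle;
it is exponential and guarded by a walk budget.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .graph import GraphError, HeteroGraph

WALK_BUDGET = 10**6


class OracleOverflowError(RuntimeError):
    """Brute-force path enumeration exceeded the walk budget."""


@dataclass
class Layer:
    """Edges connecting frontier[k-1] to frontier[k], sorted by destination."""

    src: np.ndarray  # global entity indices
    rel: np.ndarray
    dst: np.ndarray
    src_pos: np.ndarray  # positions into frontier[k-1]
    dst_pos: np.ndarray  # positions into frontier[k]
    orig_idx: np.ndarray | None = None  # positions in the pre-slice layer (alpha lookup)

    @property
    def n_edges(self) -> int:
        return len(self.src)


@dataclass
class LayeredDigraph:
    source: int
    K: int
    frontiers: list[np.ndarray]  # frontiers[k] = sorted entity indices at layer k
    layers: list[Layer] = field(default_factory=list)  # layers[k-1] connects k-1 -> k

    def frontier(self, k: int) -> np.ndarray:
        return self.frontiers[k]

    def n_edges(self) -> int:
        return sum(layer.n_edges for layer in self.layers)

    def layer_triples(self, k: int) -> set[tuple[int, int, int]]:
        """Edge set of layer k (1-based) as (src, rel, dst) triples."""
        layer = self.layers[k - 1]
        return set(zip(layer.src.tolist(), layer.rel.tolist(), layer.dst.tolist()))


def expand_layer(
    graph: HeteroGraph,
    frontier: np.ndarray,
    *,
    edge_mask: set[tuple[int, int, int]] | None = None,
    sample_neighbors: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Collect all outgoing triples of the frontier; return (src, rel, dst, next_frontier).

    ``sample_neighbors`` caps the number of out-edges kept per source entity
    (uniformly sampled with ``rng``); identity self-loops are always kept so
    frontier membership is preserved.
    """
    if len(frontier) == 0:
        raise GraphError("cannot expand an empty frontier")
    srcs, rels, dsts = [], [], []
    for e in frontier:
        lo, hi = graph.outgoing_slice(int(e))
        h = graph.head[lo:hi]
        r = graph.rel[lo:hi]
        t = graph.tail[lo:hi]
        if edge_mask:
            keep = np.array(
                [(int(hh), int(rr), int(tt)) not in edge_mask for hh, rr, tt in zip(h, r, t)],
                dtype=bool,
            ) if len(h) else np.empty(0, dtype=bool)
            h, r, t = h[keep], r[keep], t[keep]
        if sample_neighbors is not None and len(h) > sample_neighbors:
            if rng is None:
                raise GraphError("sample_neighbors requires an rng")
            is_id = (
                (r == graph.identity_relation)
                if graph.identity_relation is not None
                else np.zeros(len(h), dtype=bool)
            )
            pool = np.flatnonzero(~is_id)
            take = rng.choice(pool, size=min(sample_neighbors, len(pool)), replace=False)
            keep_idx = np.sort(np.concatenate([np.flatnonzero(is_id), take]))
            h, r, t = h[keep_idx], r[keep_idx], t[keep_idx]
        srcs.append(h)
        rels.append(r)
        dsts.append(t)
    src = np.concatenate(srcs) if srcs else np.empty(0, dtype=np.int64)
    rel = np.concatenate(rels) if rels else np.empty(0, dtype=np.int64)
    dst = np.concatenate(dsts) if dsts else np.empty(0, dtype=np.int64)
    next_frontier = np.unique(dst)
    return src, rel, dst, next_frontier


def build_union_digraph(
    graph: HeteroGraph,
    g_q: int,
    K: int,
    *,
    edge_mask: set[tuple[int, int, int]] | None = None,
    sample_neighbors: int | None = None,
    rng: np.random.Generator | None = None,
) -> LayeredDigraph:
    """Union of all K-hop relational digraphs rooted at ``g_q``.

    frontier[K] is exactly the set of entities reachable from g_q within K
    steps (identity loops pad shorter walks out to length K).
    """
    if K < 1:
        raise GraphError("K must be >= 1")
    if not 0 <= g_q < len(graph.entities):
        raise GraphError(f"entity index {g_q} out of range")
    frontiers = [np.asarray([g_q], dtype=np.int64)]
    layers: list[Layer] = []
    for _ in range(K):
        src, rel, dst, nxt = expand_layer(
            graph,
            frontiers[-1],
            edge_mask=edge_mask,
            sample_neighbors=sample_neighbors,
            rng=rng,
        )
        order = np.lexsort((src, rel, dst))  # aggregate-by-target layout
        src, rel, dst = src[order], rel[order], dst[order]
        src_pos = np.searchsorted(frontiers[-1], src)
        dst_pos = np.searchsorted(nxt, dst)
        layers.append(Layer(src, rel, dst, src_pos, dst_pos, np.arange(len(src))))
        frontiers.append(nxt)
    return LayeredDigraph(source=g_q, K=K, frontiers=frontiers, layers=layers)


def slice_pair_digraph(dg: LayeredDigraph, g_p: int) -> LayeredDigraph:
    """Backward-prune the union digraph to edges on K-length walks g_q -> g_p."""
    if g_p not in dg.frontiers[dg.K]:
        raise GraphError(f"entity {g_p} unreachable within {dg.K} hops")
    keep = {int(g_p)}
    kept_edges: list[np.ndarray] = [None] * dg.K  # type: ignore[list-item]
    frontiers: list[np.ndarray] = [None] * (dg.K + 1)  # type: ignore[list-item]
    frontiers[dg.K] = np.asarray(sorted(keep), dtype=np.int64)
    for k in range(dg.K, 0, -1):
        layer = dg.layers[k - 1]
        mask = np.isin(layer.dst, np.asarray(sorted(keep), dtype=np.int64))
        kept_edges[k - 1] = np.flatnonzero(mask)
        keep = set(layer.src[mask].tolist())
        frontiers[k - 1] = np.asarray(sorted(keep), dtype=np.int64)
    layers = []
    for k in range(1, dg.K + 1):
        layer = dg.layers[k - 1]
        idx = kept_edges[k - 1]
        src, rel, dst = layer.src[idx], layer.rel[idx], layer.dst[idx]
        src_pos = np.searchsorted(frontiers[k - 1], src)
        dst_pos = np.searchsorted(frontiers[k], dst)
        orig = layer.orig_idx[idx] if layer.orig_idx is not None else idx
        layers.append(Layer(src, rel, dst, src_pos, dst_pos, orig))
    return LayeredDigraph(source=dg.source, K=dg.K, frontiers=frontiers, layers=layers)


def enumerate_paths_bruteforce(
    graph: HeteroGraph, g_q: int, g_p: int, K: int, budget: int = WALK_BUDGET
) -> list[list[tuple[int, int, int]]]:
    """All length-K triple chains from g_q to g_p, by exhaustive DFS (test oracle)."""
    paths: list[list[tuple[int, int, int]]] = []
    counter = {"walks": 0}

    def dfs(node: int, depth: int, prefix: list[tuple[int, int, int]]) -> None:
        counter["walks"] += 1
        if counter["walks"] > budget:
            raise OracleOverflowError(f"walk budget {budget} exceeded")
        if depth == K:
            if node == g_p:
                paths.append(list(prefix))
            return
        for h, r, t in graph.outgoing(node):
            prefix.append((int(h), int(r), int(t)))
            dfs(int(t), depth + 1, prefix)
            prefix.pop()

    dfs(g_q, 0, [])
    return paths


def digraph_to_json(dg: LayeredDigraph, graph: HeteroGraph | None = None) -> str:
    """Serialize as JSON {source, K, layers:[{edges:[[src,rel,dst],...]}]}."""
    obj = {
        "source": int(dg.source),
        "K": dg.K,
        "layers": [
            {"edges": [[int(s), int(r), int(d)] for s, r, d in zip(l.src, l.rel, l.dst)]}
            for l in dg.layers
        ],
    }
    if graph is not None:
        obj["entity_ids"] = {
            int(e): graph.entities.ids[int(e)]
            for f in dg.frontiers
            for e in f
        }
    return json.dumps(obj, indent=2, sort_keys=True)


def digraph_to_dot(dg: LayeredDigraph, graph: HeteroGraph) -> str:
    """GraphViz DOT rendering with one rank per layer."""
    lines = ["digraph layered {", "  rankdir=LR;"]
    for k, frontier in enumerate(dg.frontiers):
        names = " ".join(f'"L{k}_{graph.entities.ids[int(e)]}"' for e in frontier)
        lines.append(f"  {{ rank=same; {names} }}")
    for k, layer in enumerate(dg.layers, start=1):
        for s, r, d in zip(layer.src, layer.rel, layer.dst):
            lines.append(
                f'  "L{k-1}_{graph.entities.ids[int(s)]}" -> '
                f'"L{k}_{graph.entities.ids[int(d)]}" '
                f'[label="{graph.relation_names()[int(r)]}"];'
            )
    lines.append("}")
    return "\n".join(lines)
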