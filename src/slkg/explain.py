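"""Attention-based explanation subgraphs for predicted SL pairs.

For a scored pair (primary, partner) the per-layer attention weights
recorded during the scoring forward pass are projected onto the pair's
relational digraph.  Layers 1..K-1 keep edges whose attention exceeds a
threshold (default 0.9); at the last layer the top-scoring edges (default
five) are kept.  Only edges lying on complete root-to-partner paths remain,
and each complete path is summarized by its schema signature — the
"/"-joined sequence of relation names — which acts as the inference rule the
model applied.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from .digraph import LayeredDigraph
from .graph import HeteroGraph

Triple = tuple[int, int, int]


@dataclass
class ExplanationSubgraph:
    primary: int
    partner: int
    K: int
    edges: list[dict]  # {layer, src, rel, dst, alpha}
    paths: list[list[Triple]]

    @property
    def is_empty(self) -> bool:
        return not self.paths


def schema_signature(
    path: list[Triple], relation_names: list[str], elide_identity: bool = False,
    identity_name: str = "identity",
) -> str:
    """The relation-sequence signature of a path, e.g. ``SL_GsG/involved_in/involved_in_inv``."""
    names = [relation_names[r] for _, r, _ in path]
    if elide_identity:
        names = [n for n in names if n != identity_name]
    return "/".join(names)


def extract_explanation(
    pair_digraph: LayeredDigraph,
    attention_records: list[np.ndarray],
    partner: int,
    tau: float = 0.9,
    last_layer_top: int = 5,
    last_layer_pool: str = "reachable",
    max_paths: int = 1000,
) -> ExplanationSubgraph:
    """Threshold/top-k extraction of an explanation subgraph.

    ``pair_digraph`` must be the backward slice for (source, partner);
    ``attention_records`` are the per-layer alpha arrays of the forward pass
    over the *union* digraph the slice was taken from (``orig_idx`` links
    sliced edges back to those records).  ``last_layer_pool`` chooses the
    candidate pool for the top-k rule at the last layer: ``"reachable"``
    (default) ranks only edges whose source survives the threshold rule on
    the earlier layers — the reading under which the kept last-layer edges
    can actually complete paths; ``"slice"`` ranks all last-layer edges of
    the pair digraph.
    """
    if last_layer_pool not in ("reachable", "slice"):
        raise ValueError(f"unknown last-layer pool {last_layer_pool!r}")
    K = pair_digraph.K
    kept: list[np.ndarray] = []
    reach = {int(pair_digraph.source)}
    fwd_edges: list[list[int]] = []
    for k in range(1, K + 1):
        layer = pair_digraph.layers[k - 1]
        if layer.orig_idx is None:
            raise ValueError("pair digraph lacks the edge-index link to attention records")
        alpha = attention_records[k - 1][layer.orig_idx]
        if k < K:
            kept_k = np.flatnonzero(alpha > tau)
        else:
            if last_layer_pool == "reachable":
                pool = np.asarray(
                    [i for i in range(layer.n_edges) if int(layer.src[i]) in reach],
                    dtype=np.int64,
                )
            else:
                pool = np.arange(layer.n_edges)
            order = pool[np.argsort(-alpha[pool], kind="stable")]
            kept_k = np.sort(order[:last_layer_top])
        kept.append(kept_k)
        idx = [i for i in kept_k if int(layer.src[i]) in reach]
        fwd_edges.append(idx)
        reach = {int(layer.dst[i]) for i in idx}
    keep_nodes = {int(partner)}
    final_edges: list[list[int]] = [[] for _ in range(K)]
    for k in range(K, 0, -1):
        layer = pair_digraph.layers[k - 1]
        idx = [i for i in fwd_edges[k - 1] if int(layer.dst[i]) in keep_nodes]
        final_edges[k - 1] = idx
        keep_nodes = {int(layer.src[i]) for i in idx}

    edges: list[dict] = []
    adjacency: list[dict[int, list[Triple]]] = []
    for k in range(1, K + 1):
        layer = pair_digraph.layers[k - 1]
        alpha = attention_records[k - 1][layer.orig_idx]
        adj: dict[int, list[Triple]] = {}
        for i in final_edges[k - 1]:
            s, r, d = int(layer.src[i]), int(layer.rel[i]), int(layer.dst[i])
            edges.append({"layer": k, "src": s, "rel": r, "dst": d,
                          "alpha": float(alpha[i])})
            adj.setdefault(s, []).append((s, r, d))
        adjacency.append(adj)

    paths: list[list[Triple]] = []

    def dfs(node: int, depth: int, prefix: list[Triple]) -> None:
        if len(paths) >= max_paths:
            return
        if depth == K:
            if node == int(partner):
                paths.append(list(prefix))
            return
        for triple in adjacency[depth].get(node, []):
            prefix.append(triple)
            dfs(triple[2], depth + 1, prefix)
            prefix.pop()

    dfs(int(pair_digraph.source), 0, [])
    if not paths:
        warnings.warn(
            f"no complete explanation path survives tau={tau} for pair "
            f"({pair_digraph.source}, {partner})",
            stacklevel=2,
        )
    return ExplanationSubgraph(
        primary=int(pair_digraph.source), partner=int(partner), K=K,
        edges=edges, paths=paths,
    )


def explanation_to_json(exp: ExplanationSubgraph, graph: HeteroGraph) -> str:
    ids = graph.entities.ids
    names = graph.relation_names()
    obj = {
        "primary": ids[exp.primary],
        "partner": ids[exp.partner],
        "K": exp.K,
        "edges": [
            {"layer": e["layer"], "src": ids[e["src"]], "rel": names[e["rel"]],
             "dst": ids[e["dst"]], "alpha": e["alpha"]}
            for e in exp.edges
        ],
        "paths": [
            [[ids[s], names[r], ids[d]] for s, r, d in path] for path in exp.paths
        ],
        "schemas": [schema_signature(p, names) for p in exp.paths],
    }
    return json.dumps(obj, indent=2)


def explanation_to_dot(exp: ExplanationSubgraph, graph: HeteroGraph) -> str:
    ids = graph.entities.ids
    names = graph.relation_names()
    lines = ["digraph explanation {", "  rankdir=LR;"]
    for e in exp.edges:
        lines.append(
            f'  "L{e["layer"]-1}_{ids[e["src"]]}" -> "L{e["layer"]}_{ids[e["dst"]]}" '
            f'[label="{names[e["rel"]]} ({e["alpha"]:.2f})"];'
        )
    lines.append("}")
    return "\n".join(lines)
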