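"""Naive scalar reference implementations used for cross-checking.

These deliberately avoid the vectorized code paths: the encoder reference
walks edges one at a time with Python loops over vector components, and the
ranking-metric references are written as direct set/loop arithmetic.  They
exist so that the fast implementations can be verified against an
independent route on small instances; they are never used for training or
prediction.
"""

from __future__ import annotations

import math

import numpy as np

from .digraph import LayeredDigraph
from .encoder import ModelParameters, TextEmbeddingTable


def _sig(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _act(name: str, x: float) -> float:
    if name == "relu":
        return x if x > 0.0 else 0.0
    if name == "sigmoid":
        return _sig(x)
    if name == "tanh":
        return math.tanh(x)
    raise ValueError(name)


def _matvec(x: list[float], W: np.ndarray) -> list[float]:
    """Row vector times matrix, by explicit scalar loops."""
    n_in, n_out = W.shape
    return [sum(x[i] * float(W[i, j]) for i in range(n_in)) for j in range(n_out)]


def encode_reference(
    dg: LayeredDigraph,
    params: ModelParameters,
    texts: TextEmbeddingTable | None = None,
    *,
    use_text: bool = True,
    use_attention: bool = True,
    use_gru: bool = True,
    agg_activation: str = "relu",
    gru_candidate_activation: str = "sigmoid",
) -> dict[int, list[float]]:
    """Per-entity final-layer representation, by per-edge scalar recursion.

    Returns a map global-entity-index -> d-vector for the last frontier.
    """
    d = params.d
    if use_text and texts is None:
        use_text = False
    proj = params.tensors.get("text_proj")
    tvec: dict[int, list[float]] = {}

    def text_term(e: int) -> list[float]:
        if e not in tvec:
            tvec[e] = _matvec([float(v) for v in texts.matrix[e]], proj.data)
        return tvec[e]

    state: dict[int, list[float]] = {int(dg.source): [0.0] * d}
    for k in range(1, dg.K + 1):
        layer = dg.layers[k - 1]
        W1 = params[f"W1_{k}"].data
        W2 = params[f"W2_{k}"].data
        Watt2 = params[f"Watt2_{k}"].data
        watt1 = params[f"watt1_{k}"].data
        rel_emb = params[f"rel_emb_{k}"].data
        sums: dict[int, list[float]] = {}
        for s, r, t in zip(layer.src, layer.rel, layer.dst):
            s, r, t = int(s), int(r), int(t)
            x = [state[s][i] + float(rel_emb[r, i]) for i in range(d)]
            if use_text:
                ts, tt = text_term(s), text_term(t)
                x = [x[i] + ts[i] + tt[i] for i in range(d)]
            msg = _matvec(x, W1)
            if use_attention:
                hidden = [_act("relu", v) for v in _matvec(msg, Watt2)]
                alpha = _sig(sum(hidden[i] * float(watt1[i, 0]) for i in range(d)))
            else:
                alpha = 1.0
            acc = sums.setdefault(t, [0.0] * d)
            for i in range(d):
                acc[i] += alpha * msg[i]
        new_state: dict[int, list[float]] = {}
        for t, acc in sums.items():
            z = [_act(agg_activation, v) for v in _matvec(acc, W2)]
            if not use_gru:
                new_state[t] = z
                continue
            hp = state.get(t, [0.0] * d)
            Wr, Ur, br = params[f"Wr_{k}"].data, params[f"Ur_{k}"].data, params[f"br_{k}"].data
            Wf, Uf, bf = params[f"Wf_{k}"].data, params[f"Uf_{k}"].data, params[f"bf_{k}"].data
            Wn, Un, bn = params[f"Wn_{k}"].data, params[f"Un_{k}"].data, params[f"bn_{k}"].data
            zr, hr = _matvec(z, Wr), _matvec(hp, Ur)
            zf, hf = _matvec(z, Wf), _matvec(hp, Uf)
            rgate = [_sig(zr[i] + hr[i] + float(br[i])) for i in range(d)]
            fgate = [_sig(zf[i] + hf[i] + float(bf[i])) for i in range(d)]
            zn, hn = _matvec(z, Wn), _matvec(hp, Un)
            ngate = [
                _act(gru_candidate_activation, zn[i] + rgate[i] * hn[i] + float(bn[i]))
                for i in range(d)
            ]
            new_state[t] = [
                (1.0 - fgate[i]) * ngate[i] + fgate[i] * hp[i] for i in range(d)
            ]
        state = new_state
    return state


def score_reference(h: dict[int, list[float]], params: ModelParameters,
                    gene_indices, n_entities: int) -> np.ndarray:
    """Scalar-loop scoring: W_ff . h + b_ff for reached genes, 0 elsewhere."""
    W_ff = params["W_ff"].data
    b_ff = float(params["b_ff"].data[0])
    scores = np.zeros(n_entities)
    gene_set = set(int(g) for g in gene_indices)
    for e, vec in h.items():
        if e in gene_set:
            scores[e] = sum(vec[i] * float(W_ff[i, 0]) for i in range(len(vec))) + b_ff
    return scores


def ndcg_reference(ranked: list[int], relevant: set[int], N: int) -> float:
    """Binary-relevance NDCG@N by direct summation (independent route)."""
    if not relevant:
        return 0.0
    dcg = 0.0
    for pos, gene in enumerate(ranked[:N], start=1):
        if gene in relevant:
            dcg += 1.0 / math.log2(pos + 1)
    ideal = 0.0
    for pos in range(1, min(len(relevant), N) + 1):
        ideal += 1.0 / math.log2(pos + 1)
    return dcg / ideal


def precision_recall_reference(
    ranked: list[int], relevant: set[int], N: int
) -> tuple[float, float]:
    hits = len({g for g in ranked[:N]} & relevant)
    precision = hits / N
    recall = hits / len(relevant) if relevant else 0.0
    return precision, recall
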