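"""Layered semantic encoder over a relational digraph.

For a primary gene's layered digraph, layer k computes, for every edge
(e_i, r, e_o) from frontier k-1 to frontier k:

    message  m = (h_{e_i}^{k-1} + rel_emb_k[r] [+ P(T_{e_i}) + P(T_{e_o})]) W1_k
    gate     alpha = sigmoid( ReLU(m Watt2_k) . watt1_k )            in (0, 1)

then aggregates messages per target entity,

    z_{e_o} = act( (sum_edges alpha * m) W2_k )

and finally passes z through a GRU whose previous state is the entity's
layer-(k-1) representation (zero if the entity was not on the previous
frontier):

    r = sig(z Wr + h' Ur + br);  f = sig(z Wf + h' Uf + bf)
    n = cand( z Wn + r * (h' Un) + bn );   h = (1 - f) * n + f * h'

All linear maps act on row vectors by right-multiplication (x W).  Textual
semantics enter through a learned projection P of per-entity text embeddings;
with no text table the message reduces to the structure-only form.  The three
ablations (no text, no attention with alpha == 1, no GRU with h = z) compose
independently.

Per-edge attention weights are recorded during the forward pass so the
explainer can reuse the exact alphas that produced a prediction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .digraph import LayeredDigraph

_ACTIVATIONS = {"relu": ad.relu, "sigmoid": ad.sigmoid, "tanh": ad.tanh}


class EncoderError(ValueError):
    pass


@dataclass
class TextEmbeddingTable:
    """Per-entity text embeddings with a provenance tag.

    provenance is one of ``pretrained`` (externally computed, e.g. from a
    biomedical language model), ``synthetic`` (seeded random vectors used in
    simulation studies) or ``absent``.
    """

    matrix: np.ndarray  # (n_entities, d_text)
    provenance: str = "pretrained"

    @property
    def d_text(self) -> int:
        return self.matrix.shape[1]

    def rows(self, idx: np.ndarray) -> np.ndarray:
        if np.any(idx >= len(self.matrix)):
            raise EncoderError(
                "text table marked %r is missing vectors for some entities"
                % self.provenance
            )
        return self.matrix[idx]

    @classmethod
    def synthetic(cls, n_entities: int, d_text: int = 32, seed: int = 0) -> "TextEmbeddingTable":
        rng = np.random.default_rng(seed)
        m = rng.standard_normal((n_entities, d_text))
        m /= np.linalg.norm(m, axis=1, keepdims=True)
        return cls(m, provenance="synthetic")

    @classmethod
    def from_tsv(cls, path, entity_index: dict[str, int], n_entities: int) -> "TextEmbeddingTable":
        rows = {}
        with open(path, "rt", encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                rows[parts[0]] = np.asarray([float(x) for x in parts[1:]])
        d_text = len(next(iter(rows.values())))
        m = np.zeros((n_entities, d_text))
        for entity_id, vec in rows.items():
            m[entity_index[entity_id]] = vec
        return cls(m, provenance="pretrained")


class ModelParameters:
    """All learnable weights, stored as named autodiff tensors.

    Per layer k = 1..K: ``W1_k``, ``W2_k``, ``Watt2_k`` (d x d), ``watt1_k``
    (d x 1), ``rel_emb_k`` (n_relations x d) and the six GRU matrices plus
    three biases.  Shared: optional ``text_proj`` (d_text x d) and the scorer
    weights ``W_ff`` (d x 1), ``b_ff`` (scalar).
    """

    def __init__(self, K: int, d: int, n_relations: int, d_text: int | None = None,
                 seed: int = 0):
        self.K = K
        self.d = d
        self.n_relations = n_relations
        self.d_text = d_text
        rng = np.random.default_rng(seed)

        def mat(n_in, n_out):
            limit = np.sqrt(6.0 / (n_in + n_out))
            return Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)),
                          requires_grad=True)

        self.tensors: dict[str, Tensor] = {}
        t = self.tensors
        for k in range(1, K + 1):
            t[f"W1_{k}"] = mat(d, d)
            t[f"W2_{k}"] = mat(d, d)
            t[f"Watt2_{k}"] = mat(d, d)
            # open-gate init (cf. LSTM forget-bias warm start): a positive
            # readout over the non-negative ReLU features starts every edge
            # gate high, and training selectively closes uninformative edges;
            # a symmetric init leaves half the gates nearly shut, which the
            # few optimizer steps of a small run cannot reopen
            t[f"watt1_{k}"] = Tensor(np.abs(rng.standard_normal((d, 1))) * 2.0,
                                     requires_grad=True)
            t[f"rel_emb_{k}"] = Tensor(
                rng.standard_normal((n_relations, d)) / np.sqrt(d), requires_grad=True
            )
            for gate in ("r", "f", "n"):
                t[f"W{gate}_{k}"] = mat(d, d)
                t[f"U{gate}_{k}"] = mat(d, d)
                t[f"b{gate}_{k}"] = Tensor(np.zeros(d), requires_grad=True)
        if d_text is not None:
            t["text_proj"] = mat(d_text, d)
        t["W_ff"] = mat(d, 1)
        t["b_ff"] = Tensor(np.zeros(1), requires_grad=True)

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def zero_grad(self) -> None:
        for tensor in self.tensors.values():
            tensor.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.tensors.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in state.items():
            if k not in self.tensors:
                raise EncoderError(f"unexpected parameter {k!r} in checkpoint")
            if self.tensors[k].data.shape != v.shape:
                raise EncoderError(
                    f"shape mismatch for {k!r}: "
                    f"{self.tensors[k].data.shape} vs {v.shape}"
                )
            self.tensors[k].data = np.asarray(v, dtype=np.float64)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict(),
                 __meta__=np.asarray([self.K, self.d, self.n_relations,
                                      -1 if self.d_text is None else self.d_text]))

    @classmethod
    def load(cls, path) -> "ModelParameters":
        with np.load(path) as data:
            K, d, n_rel, d_text = (int(x) for x in data["__meta__"])
            params = cls(K, d, n_rel, None if d_text < 0 else d_text)
            params.load_state_dict(
                {k: data[k] for k in data.files if k != "__meta__"}
            )
        return params


@dataclass
class EncodeResult:
    """Final-layer representations plus the per-layer attention record."""

    h: Tensor  # (|frontier[K]|, d), rows aligned with dg.frontiers[K]
    frontier: np.ndarray
    alphas: list[np.ndarray] = field(default_factory=list)  # per layer, per edge


def _prev_positions(prev_frontier: np.ndarray, frontier: np.ndarray) -> np.ndarray:
    """Position of each frontier entity in the previous frontier; len(prev) if absent."""
    pos = np.searchsorted(prev_frontier, frontier)
    pos_clip = np.minimum(pos, len(prev_frontier) - 1) if len(prev_frontier) else pos * 0
    present = (pos < len(prev_frontier)) & (
        prev_frontier[pos_clip] == frontier if len(prev_frontier) else False
    )
    return np.where(present, pos, len(prev_frontier)).astype(np.int64)


def encode(
    dg: LayeredDigraph,
    params: ModelParameters,
    texts: TextEmbeddingTable | None = None,
    *,
    training: bool = False,
    dropout: float = 0.0,
    rng: np.random.Generator | None = None,
    use_text: bool = True,
    use_attention: bool = True,
    use_gru: bool = True,
    agg_activation: str = "relu",
    gru_candidate_activation: str = "sigmoid",
) -> EncodeResult:
    """Run the layered encoder over ``dg`` and return final representations.

    The source gene starts from the zero vector; representations exist exactly
    for the entities of each frontier.  Dropout (on z, before the recurrent
    update) is active only with ``training=True``.
    """
    if params.K != dg.K:
        raise EncoderError(f"parameter depth K={params.K} != digraph K={dg.K}")
    if use_text and texts is not None and texts.provenance == "absent":
        texts = None
    if use_text and texts is None:
        use_text = False
    if use_text and "text_proj" not in params.tensors:
        raise EncoderError("text table supplied but parameters lack text_proj")
    act = _ACTIVATIONS[agg_activation]
    cand = _ACTIVATIONS[gru_candidate_activation]
    if training and dropout > 0.0 and rng is None:
        raise EncoderError("training with dropout requires an rng")

    h = Tensor(np.zeros((1, params.d)))  # frontier[0] = [g_q], query state = 0
    alphas: list[np.ndarray] = []
    for k in range(1, dg.K + 1):
        layer = dg.layers[k - 1]
        frontier = dg.frontiers[k]
        h_src = ad.gather_rows(h, layer.src_pos)
        rel_e = ad.gather_rows(params[f"rel_emb_{k}"], layer.rel)
        msg_in = h_src + rel_e
        if use_text:
            t_src = Tensor(texts.rows(layer.src))
            t_dst = Tensor(texts.rows(layer.dst))
            proj = params["text_proj"]
            msg_in = msg_in + (t_src @ proj) + (t_dst @ proj)
        msg = msg_in @ params[f"W1_{k}"]
        if use_attention:
            hidden = ad.relu(msg @ params[f"Watt2_{k}"])
            alpha = ad.sigmoid(hidden @ params[f"watt1_{k}"])  # (E, 1)
        else:
            alpha = Tensor(np.ones((layer.n_edges, 1)))
        alphas.append(alpha.data.ravel().copy())
        agg = ad.segment_sum(alpha * msg, layer.dst_pos, len(frontier))
        z = act(agg @ params[f"W2_{k}"])
        if training and dropout > 0.0:
            mask = rng.binomial(1, 1.0 - dropout, size=z.data.shape) / (1.0 - dropout)
            z = z * mask
        if use_gru:
            prev_pos = _prev_positions(dg.frontiers[k - 1], frontier)
            hp = ad.gather_rows(ad.pad_zero_row(h), prev_pos)
            r = ad.sigmoid(z @ params[f"Wr_{k}"] + hp @ params[f"Ur_{k}"] + params[f"br_{k}"])
            f = ad.sigmoid(z @ params[f"Wf_{k}"] + hp @ params[f"Uf_{k}"] + params[f"bf_{k}"])
            n = cand(z @ params[f"Wn_{k}"] + r * (hp @ params[f"Un_{k}"]) + params[f"bn_{k}"])
            h = (1.0 - f) * n + f * hp
        else:
            h = z
    return EncodeResult(h=h, frontier=dg.frontiers[dg.K], alphas=alphas)
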