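"""Synthetic-lethality partner ranking as a scikit-learn style estimator.

``SLPartnerRanker`` wraps the whole pipeline — per-primary layered digraph
construction, the attentive GRU encoder, feed-forward scoring, multi-class
cross-entropy training with Adam, filtered top-N evaluation and
attention-based explanation — behind a ``fit`` / ``predict`` / ``explain``
surface with sklearn parameter semantics (``get_params`` / ``set_params``,
fitted attributes carrying a trailing underscore).

Training groups supervision by primary gene: one optimizer step per batch of
(at most) ``batch_size`` distinct primaries, each contributing its positives
to the softmax loss.  To prevent a trivial shortcut through identity padding
(SL edge then two identity hops), the direct SL edges between a primary and
its supervised positives are masked out of that primary's message digraph
during training.
"""

from __future__ import annotations

import copy
import time

import numpy as np
from sklearn.base import BaseEstimator

from .digraph import LayeredDigraph, build_union_digraph, slice_pair_digraph
from .encoder import EncodeResult, ModelParameters, TextEmbeddingTable, encode
from .explain import ExplanationSubgraph, extract_explanation
from .graph import GraphError, HeteroGraph
from .metrics import MetricReport, RankedPrediction, evaluate_rankings, rank_candidates
from .scorer import ScoredBatchItem, multiclass_loss, reached_gene_scores


class Adam:
    """Adam with classic L2 regularization folded into the gradient."""

    def __init__(self, lr: float = 5e-4, weight_decay: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.lr = lr
        self.weight_decay = weight_decay
        self.betas = betas
        self.eps = eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}

    def step(self, params: ModelParameters) -> None:
        self.t += 1
        b1, b2 = self.betas
        for name, tensor in params.tensors.items():
            if tensor.grad is None:
                continue
            g = tensor.grad + self.weight_decay * tensor.data
            m = self.m.setdefault(name, np.zeros_like(tensor.data))
            v = self.v.setdefault(name, np.zeros_like(tensor.data))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            m_hat = m / (1 - b1 ** self.t)
            v_hat = v / (1 - b2 ** self.t)
            tensor.data -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


class SLPartnerRanker(BaseEstimator):
    """Rank candidate SL partner genes for primary genes by digraph reasoning.

    Parameters
    ----------
    n_layers : depth K of the relational digraphs (path length).
    dim : latent embedding size d.
    batch_size : number of distinct primary genes per optimizer step.
    max_epochs, learning_rate, weight_decay, dropout : optimization settings.
    use_text / use_attention / use_gru : ablation switches (full model: all on).
    neighbor_sample : if set, uniformly sample at most this many non-identity
        out-edges per source per layer (seeded), emulating sampled variants.
    loss_candidates : ``"all"`` normalizes the training softmax over the whole
        gene vocabulary; ``"positives"`` over the primary's training partners.
    agg_activation / gru_candidate_activation : configurable nonlinearities.
    seed : master seed; every stochastic choice derives from it.
    """

    def __init__(
        self,
        n_layers: int = 3,
        dim: int = 48,
        batch_size: int = 50,
        max_epochs: int = 50,
        dropout: float = 0.5,
        learning_rate: float = 5e-4,
        weight_decay: float = 1e-4,
        use_text: bool = True,
        use_attention: bool = True,
        use_gru: bool = True,
        neighbor_sample: int | None = None,
        loss_candidates: str = "all",
        agg_activation: str = "relu",
        gru_candidate_activation: str = "sigmoid",
        val_every: int = 1,
        seed: int = 0,
        verbose: bool = False,
    ):
        self.n_layers = n_layers
        self.dim = dim
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.dropout = dropout
        self.learning_rate = learning_rate
        self.weight_decay = weight_decay
        self.use_text = use_text
        self.use_attention = use_attention
        self.use_gru = use_gru
        self.neighbor_sample = neighbor_sample
        self.loss_candidates = loss_candidates
        self.agg_activation = agg_activation
        self.gru_candidate_activation = gru_candidate_activation
        self.val_every = val_every
        self.seed = seed
        self.verbose = verbose

    # -- helpers ----------------------------------------------------------

    def _as_index_pairs(self, graph: HeteroGraph, pairs) -> list[tuple[int, int]]:
        out = []
        for q, p in pairs:
            qi = graph.entities.index_of(q) if isinstance(q, str) else int(q)
            pi = graph.entities.index_of(p) if isinstance(p, str) else int(p)
            out.append((qi, pi))
        return out

    def _encode(self, dg: LayeredDigraph, *, training: bool,
                rng: np.random.Generator | None = None) -> EncodeResult:
        return encode(
            dg,
            self.params_,
            self.texts_,
            training=training,
            dropout=self.dropout if training else 0.0,
            rng=rng,
            use_text=self.use_text,
            use_attention=self.use_attention,
            use_gru=self.use_gru,
            agg_activation=self.agg_activation,
            gru_candidate_activation=self.gru_candidate_activation,
        )

    def _train_digraph(self, graph: HeteroGraph, primary: int,
                       positives: list[int]) -> LayeredDigraph:
        """Digraph for one supervised forward pass.

        Only the direct SL edges between the primary and the positives being
        scored in this pass are masked (the anti-shortcut rule); edges to the
        primary's other known partners stay, since they carry the genuine
        multi-hop support for the pass's own positives.
        """
        mask = None
        if graph.sl_relation is not None:
            mask = set()
            for p in positives:
                mask.add((primary, graph.sl_relation, p))
                mask.add((p, graph.sl_relation, primary))
        rng = None
        if self.neighbor_sample is not None:
            rng = np.random.default_rng((self.seed * 1_000_003 + primary) % (2**31))
        return build_union_digraph(
            graph, primary, self.n_layers,
            edge_mask=mask, sample_neighbors=self.neighbor_sample, rng=rng,
        )

    def _eval_digraph(self, graph: HeteroGraph, primary: int) -> LayeredDigraph:
        cache = self._eval_cache.setdefault(id(graph), {})
        if primary not in cache:
            cache[primary] = build_union_digraph(graph, primary, self.n_layers)
        return cache[primary]

    # -- fitting ----------------------------------------------------------

    def fit(self, graph: HeteroGraph, train_pairs, val_pairs=None,
            texts: TextEmbeddingTable | None = None, genes=None):
        """Train on oriented supervision pairs over an augmented graph.

        ``train_pairs`` and ``val_pairs`` are oriented (primary, partner)
        pairs (entity IDs or indices); callers usually expand undirected SL
        pairs with :func:`slkg.splits.both_orientations`.  ``genes`` fixes
        the candidate vocabulary V (defaults to all Gene-typed entities).
        """
        if not graph.augmented:
            raise GraphError("fit requires an augmented graph (call graph.augment)")
        self.graph_ = graph
        self.texts_ = texts if (self.use_text and texts is not None) else None
        if genes is None:
            self.genes_ = graph.entities.gene_indices()
        else:
            self.genes_ = np.asarray(
                sorted(
                    graph.entities.index_of(g) if isinstance(g, str) else int(g)
                    for g in genes
                ),
                dtype=np.int64,
            )
        pairs = self._as_index_pairs(graph, train_pairs)
        positives: dict[int, list[int]] = {}
        for q, p in pairs:
            positives.setdefault(q, []).append(p)
        primaries = sorted(positives)

        d_text = self.texts_.d_text if self.texts_ is not None else None
        self.params_ = ModelParameters(
            self.n_layers, self.dim, graph.n_relations, d_text, seed=self.seed
        )
        self._eval_cache: dict[int, dict[int, LayeredDigraph]] = {}
        rng = np.random.default_rng(self.seed)
        optimizer = Adam(self.learning_rate, self.weight_decay)

        # one masked digraph per supervised pair: masking is pair-specific so
        # that support paths through the primary's other partners survive
        digraphs = {
            (q, p): self._train_digraph(graph, q, [p])
            for q in primaries
            for p in positives[q]
        }
        val_oriented = (
            self._as_index_pairs(graph, val_pairs) if val_pairs is not None else None
        )

        self.history_ = []
        self.n_steps_ = 0
        best = (-np.inf, None, -1)
        for epoch in range(1, self.max_epochs + 1):
            t0 = time.time()
            order = rng.permutation(len(primaries))
            epoch_loss, n_pairs = 0.0, 0
            for start in range(0, len(order), self.batch_size):
                batch = [primaries[i] for i in order[start:start + self.batch_size]]
                items: list[ScoredBatchItem] = []
                item_positives: list[list[int]] = []
                for q in batch:
                    for p in positives[q]:
                        enc = self._encode(digraphs[(q, p)], training=True, rng=rng)
                        items.append(
                            reached_gene_scores(enc, self.params_, self.genes_, q)
                        )
                        item_positives.append([p])
                loss = multiclass_loss(items, item_positives, self.loss_candidates)
                batch_pairs = sum(len(positives[q]) for q in batch)
                loss = loss * (1.0 / batch_pairs)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        "loss became non-finite; try a lower learning_rate "
                        "(the printed tuning range is 1e-4 to 1e-3)"
                    )
                self.params_.zero_grad()
                loss.backward()
                optimizer.step(self.params_)
                self.n_steps_ += 1
                epoch_loss += float(loss.data) * batch_pairs
                n_pairs += batch_pairs
            record = {
                "epoch": epoch,
                "loss": epoch_loss / max(n_pairs, 1),
                "seconds": time.time() - t0,
            }
            if val_oriented and epoch % self.val_every == 0:
                report = self._evaluate_oriented(
                    graph, val_oriented, exclude=positives, Ns=(10,)
                )
                record["val_ndcg@10"] = report["ndcg@10"]
                if report["ndcg@10"] > best[0]:
                    best = (report["ndcg@10"], copy.deepcopy(self.params_.state_dict()),
                            epoch)
            self.history_.append(record)
            if self.verbose:
                print({k: (round(v, 4) if isinstance(v, float) else v)
                       for k, v in record.items()})
        if best[1] is not None:
            self.params_.load_state_dict(best[1])
            self.best_epoch_ = best[2]
        else:
            self.best_epoch_ = self.max_epochs
        return self

    # -- inference --------------------------------------------------------

    def predict_scores(self, primary, graph: HeteroGraph | None = None) -> np.ndarray:
        """Zero-filled score vector over all entities for one primary gene."""
        graph = graph or self.graph_
        q = graph.entities.index_of(primary) if isinstance(primary, str) else int(primary)
        dg = self._eval_digraph(graph, q)
        enc = self._encode(dg, training=False)
        item = reached_gene_scores(enc, self.params_, self.genes_, q)
        scores = np.zeros(len(graph.entities))
        scores[item.reached_genes] = item.scores.data.ravel()
        return scores

    def rank(self, primary, known=(), relevant=(), graph: HeteroGraph | None = None,
             genes=None) -> RankedPrediction:
        graph = graph or self.graph_
        q = graph.entities.index_of(primary) if isinstance(primary, str) else int(primary)
        to_idx = lambda g: graph.entities.index_of(g) if isinstance(g, str) else int(g)
        gene_idx = self.genes_ if genes is None else np.asarray(sorted(map(to_idx, genes)))
        return rank_candidates(
            self.predict_scores(q, graph), gene_idx,
            {to_idx(g) for g in known}, q, {to_idx(g) for g in relevant},
        )

    def _evaluate_oriented(
        self, graph: HeteroGraph, oriented: list[tuple[int, int]],
        exclude: dict[int, list[int]] | None = None,
        Ns: tuple[int, ...] = (10, 20, 50),
        genes: np.ndarray | None = None,
        precision_denominator: str = "N",
    ) -> MetricReport:
        relevant: dict[int, set[int]] = {}
        for q, p in oriented:
            relevant.setdefault(q, set()).add(p)
        known_graph = graph.sl_pairs()
        known_map: dict[int, set[int]] = {}
        for u, v in known_graph:
            known_map.setdefault(u, set()).add(v)
            known_map.setdefault(v, set()).add(u)
        rps = []
        gene_idx = self.genes_ if genes is None else genes
        for q in sorted(relevant):
            known = set(known_map.get(q, set()))
            if exclude:
                known |= set(exclude.get(q, []))
            known -= relevant[q]
            scores = np.zeros(len(graph.entities))
            dg = self._eval_digraph(graph, q)
            enc = self._encode(dg, training=False)
            item = reached_gene_scores(enc, self.params_, gene_idx, q)
            scores[item.reached_genes] = item.scores.data.ravel()
            rps.append(rank_candidates(scores, gene_idx, known, q, relevant[q]))
        return evaluate_rankings(rps, Ns, precision_denominator)

    def evaluate(self, test_pairs, exclude: dict | None = None,
                 graph: HeteroGraph | None = None, Ns=(10, 20, 50),
                 genes=None, precision_denominator: str = "N") -> MetricReport:
        """Macro-averaged filtered ranking metrics over the test primaries.

        ``exclude`` maps primary -> additional genes (beyond the message
        graph's known partners and self) to drop before ranking, typically
        the train/validation partners of that primary.
        """
        graph = graph or self.graph_
        oriented = self._as_index_pairs(graph, test_pairs)
        exclude_idx = None
        if exclude:
            to_idx = lambda g: graph.entities.index_of(g) if isinstance(g, str) else int(g)
            exclude_idx = {to_idx(q): [to_idx(g) for g in gs] for q, gs in exclude.items()}
        gene_idx = None
        if genes is not None:
            to_idx = lambda g: graph.entities.index_of(g) if isinstance(g, str) else int(g)
            gene_idx = np.asarray(sorted(map(to_idx, genes)), dtype=np.int64)
        return self._evaluate_oriented(
            graph, oriented, exclude_idx, tuple(Ns), gene_idx, precision_denominator
        )

    def explain(self, primary, partner, tau: float = 0.9, last_layer_top: int = 5,
                graph: HeteroGraph | None = None) -> ExplanationSubgraph:
        """Extract the attention explanation subgraph for one predicted pair."""
        graph = graph or self.graph_
        to_idx = lambda g: graph.entities.index_of(g) if isinstance(g, str) else int(g)
        q, p = to_idx(primary), to_idx(partner)
        dg = self._eval_digraph(graph, q)
        if p not in dg.frontiers[dg.K]:
            import warnings

            warnings.warn(f"pair ({primary}, {partner}) unreachable within "
                          f"{self.n_layers} hops; empty explanation", stacklevel=2)
            return ExplanationSubgraph(primary=q, partner=p, K=self.n_layers,
                                       edges=[], paths=[])
        enc = self._encode(dg, training=False)
        pair_dg = slice_pair_digraph(dg, p)
        return extract_explanation(pair_dg, enc.alphas, p, tau=tau,
                                   last_layer_top=last_layer_top)
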