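"""Scoring decoder and multi-class training loss.

A candidate gene reached at the last layer is scored by a feed-forward
readout of its final representation, s(g_q, g_p) = W_ff . h + b_ff; genes
not reached within K hops score exactly zero.  Training treats every gene in
the candidate vocabulary as a class and minimizes cross-entropy of each
supervised partner under a softmax over that vocabulary (unreached genes
participate with their pinned zero scores).  A configurable alternative
restricts the softmax to the primary gene's own training partners.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import EncodeResult, ModelParameters


class ScorerError(ValueError):
    pass


@dataclass
class ScoreVector:
    """Scores for every gene in the vocabulary, for one primary gene.

    ``scores`` is indexed by global entity index (zeros off the gene set and
    for unreached genes); ``reached`` lists the genes present on the last
    frontier.
    """

    primary: int
    scores: np.ndarray
    reached: np.ndarray
    gene_indices: np.ndarray


@dataclass
class ScoredBatchItem:
    """Differentiable scores for one primary gene (training path)."""

    primary: int
    reached_genes: np.ndarray  # global entity indices, sorted
    scores: Tensor  # (m, 1) scores aligned with reached_genes
    n_unreached: int  # genes of V absent from the last frontier (score 0)


def reached_gene_scores(
    enc: EncodeResult, params: ModelParameters, gene_indices: np.ndarray, primary: int
) -> ScoredBatchItem:
    """Feed-forward scores for the genes on the last frontier (autodiff path)."""
    gene_indices = np.asarray(gene_indices, dtype=np.int64)
    mask = np.isin(enc.frontier, gene_indices)
    rows = np.flatnonzero(mask)
    reached = enc.frontier[rows]
    h_genes = ad.gather_rows(enc.h, rows)
    scores = h_genes @ params["W_ff"] + params["b_ff"]
    return ScoredBatchItem(
        primary=primary,
        reached_genes=reached,
        scores=scores,
        n_unreached=len(gene_indices) - len(reached),
    )


def score_vector(item: ScoredBatchItem, n_entities: int) -> ScoreVector:
    """Materialize a full zero-filled score vector (inference path)."""
    scores = np.zeros(n_entities)
    scores[item.reached_genes] = item.scores.data.ravel()
    return ScoreVector(
        primary=item.primary,
        scores=scores,
        reached=item.reached_genes,
        gene_indices=None,  # filled by callers that track V explicitly
    )


def multiclass_loss(
    items: list[ScoredBatchItem],
    positives: dict[int, list[int]] | list[list[int]],
    candidates: str = "all",
) -> Tensor:
    """Cross-entropy over candidate classes, summed over supervised pairs.

    ``positives`` maps each primary gene to its supervised partner genes
    (or is a list aligned with ``items``, for callers that score the same
    primary several times under different edge masks).  With
    ``candidates="all"`` the softmax normalizer runs over the whole gene
    vocabulary (unreached genes contribute exp(0)); with
    ``candidates="positives"`` it runs over the primary's training partners
    only (the narrower literal reading).
    """
    if candidates not in ("all", "positives"):
        raise ScorerError(f"unknown candidate mode {candidates!r}")
    total: Tensor | None = None
    for item_idx, item in enumerate(items):
        if isinstance(positives, dict):
            pos = positives.get(item.primary, [])
        else:
            pos = positives[item_idx]
        if not pos:
            continue
        lookup = {int(g): i for i, g in enumerate(item.reached_genes)}
        if candidates == "all":
            lse = ad.logsumexp_with_zeros(item.scores, item.n_unreached)
        else:
            rows = [lookup[int(p)] for p in pos if int(p) in lookup]
            n_zero = len(pos) - len(rows)
            if rows:
                lse = ad.logsumexp_with_zeros(
                    ad.gather_rows(item.scores, rows), n_zero
                )
            else:
                lse = Tensor(np.log(float(n_zero)))  # all positives pinned at 0
        for p in pos:
            if int(p) in lookup:
                s_p = ad.tsum(ad.gather_rows(item.scores, [lookup[int(p)]]))
            else:
                s_p = Tensor(0.0)  # unreached positive: pinned zero score
            term = lse - s_p
            total = term if total is None else total + term
    if total is None:
        raise ScorerError("batch contains no supervised positives")
    return total
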