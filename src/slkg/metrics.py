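"""Filtered top-N ranking and NDCG / Precision / Recall over primary genes.

For each primary gene, its known partners and itself are removed before
ranking; the remaining candidates are sorted by descending score with ties
broken by ascending gene index (a total, reproducible order).  Metrics use
binary relevance, log-2 discounting for DCG and an ideal DCG truncated at
min(|relevant|, N); final numbers are macro-averaged over primary genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class RankedPrediction:
    primary: int
    ranked: np.ndarray  # candidate genes, best first
    scores: np.ndarray  # scores aligned with ranked
    relevant: frozenset[int] = frozenset()
    excluded: frozenset[int] = frozenset()


@dataclass
class MetricReport:
    metrics: dict[str, float]
    per_primary: pd.DataFrame
    Ns: tuple[int, ...] = (10, 20, 50)

    def __getitem__(self, key: str) -> float:
        return self.metrics[key]


def rank_candidates(
    scores: np.ndarray,
    gene_indices: np.ndarray,
    known: set[int],
    primary: int,
    relevant: set[int] | frozenset[int] = frozenset(),
) -> RankedPrediction:
    """Filtered descending ranking of candidate genes for one primary gene.

    ``scores`` is indexed by global entity index; ``gene_indices`` defines
    the candidate vocabulary V.  Known partners and the primary itself are
    excluded before sorting.
    """
    gene_indices = np.asarray(gene_indices, dtype=np.int64)
    excluded = set(int(g) for g in known) | {int(primary)}
    keep = np.asarray([int(g) not in excluded for g in gene_indices], dtype=bool)
    cand = gene_indices[keep]
    cand_scores = scores[cand]
    order = np.lexsort((cand, -cand_scores))  # score desc, index asc
    return RankedPrediction(
        primary=int(primary),
        ranked=cand[order],
        scores=cand_scores[order],
        relevant=frozenset(int(g) for g in relevant),
        excluded=frozenset(excluded),
    )


def ndcg_at_n(rp: RankedPrediction, N: int) -> float:
    """Binary-relevance NDCG@N; 0 when the relevant set is empty."""
    if not rp.relevant:
        return 0.0
    top = rp.ranked[:N]
    rel = np.asarray([int(g) in rp.relevant for g in top], dtype=float)
    discounts = 1.0 / np.log2(np.arange(2, len(top) + 2))
    dcg = float(rel @ discounts)
    n_ideal = min(len(rp.relevant), N)
    idcg = float(np.sum(1.0 / np.log2(np.arange(2, n_ideal + 2))))
    return dcg / idcg


def precision_recall_at_n(
    rp: RankedPrediction, N: int, denominator: str = "N"
) -> tuple[float, float]:
    """(Precision@N, Recall@N) with binary relevance.

    ``denominator`` selects the precision normalizer: the standard ``"N"``,
    or ``"min"`` for min(N, |relevant|) (a variant some rankings literatures
    use, under which Precision@N == Recall@N whenever |relevant| <= N).
    """
    hits = len(set(int(g) for g in rp.ranked[:N]) & rp.relevant)
    if denominator == "N":
        denom = N
    elif denominator == "min":
        denom = min(N, len(rp.relevant)) if rp.relevant else N
    else:
        raise ValueError(f"unknown precision denominator {denominator!r}")
    precision = hits / denom if denom else 0.0
    recall = hits / len(rp.relevant) if rp.relevant else 0.0
    return precision, recall


def evaluate_rankings(
    rps: list[RankedPrediction],
    Ns: tuple[int, ...] = (10, 20, 50),
    precision_denominator: str = "N",
) -> MetricReport:
    """Macro-average NDCG/Precision/Recall over primary genes."""
    rows = []
    for rp in rps:
        row: dict[str, float] = {"primary": rp.primary, "n_relevant": len(rp.relevant)}
        for N in Ns:
            p, r = precision_recall_at_n(rp, N, precision_denominator)
            row[f"ndcg@{N}"] = ndcg_at_n(rp, N)
            row[f"precision@{N}"] = p
            row[f"recall@{N}"] = r
        rows.append(row)
    per_primary = pd.DataFrame(rows)
    metrics = {
        col: float(per_primary[col].mean())
        for col in per_primary.columns
        if col not in ("primary", "n_relevant")
    }
    return MetricReport(metrics=metrics, per_primary=per_primary, Ns=tuple(Ns))


def rankings_frame(rps: list[RankedPrediction], top_n: int | None = None) -> pd.DataFrame:
    """Long-format dump: primary, rank, gene, score, is_relevant."""
    rows = []
    for rp in rps:
        limit = len(rp.ranked) if top_n is None else min(top_n, len(rp.ranked))
        for pos in range(limit):
            g = int(rp.ranked[pos])
            rows.append(
                {
                    "primary": rp.primary,
                    "rank": pos + 1,
                    "gene": g,
                    "score": float(rp.scores[pos]),
                    "is_relevant": g in rp.relevant,
                }
            )
    return pd.DataFrame(rows)
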