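"""Transductive and inductive train/validation/test splits of SL pairs.

Transductive: undirected pairs are shuffled and split 7:1:2 into train /
validation / test supervision sets; 60% of the training pairs are sampled as
"known" pairs that enter the message graph as SL edges.  Inductive: the SL
gene set is partitioned 6:4 into train and test genes with disjoint sub-KGs
induced by dropping the other side's gene entities; train-side pairs split
4:3:3 into known / train-supervision / validation, test-side pairs split 4:6
into known / test-supervision; pairs straddling the gene partition are
dropped (and counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import EntityTable, HeteroGraph, Relation

Pair = tuple[str, str]


class SplitError(ValueError):
    pass


@dataclass
class SplitSpec:
    mode: str = "transductive"  # or "inductive"
    seed: int = 0
    transductive_ratios: tuple[float, float, float] = (0.7, 0.1, 0.2)
    known_fraction: float = 0.6
    inductive_gene_ratio: float = 0.6
    inductive_train_ratios: tuple[float, float, float] = (0.4, 0.3, 0.3)  # K:T:V
    inductive_test_ratios: tuple[float, float] = (0.4, 0.6)  # K:T


@dataclass
class TransductiveSplit:
    known: list[Pair]
    train: list[Pair]
    val: list[Pair]
    test: list[Pair]


@dataclass
class InductiveSplit:
    train_genes: set[str]
    test_genes: set[str]
    known_train: list[Pair]
    train: list[Pair]
    val: list[Pair]
    known_test: list[Pair]
    test: list[Pair]
    n_dropped_cross: int = 0


def dedup_pairs(pairs: list[Pair]) -> list[Pair]:
    """Canonicalize to sorted undirected pairs, deduplicated, order-stable."""
    seen: dict[Pair, None] = {}
    for u, v in pairs:
        key = (u, v) if u <= v else (v, u)
        seen.setdefault(key, None)
    return list(seen)


def split_transductive(pairs: list[Pair], spec: SplitSpec) -> TransductiveSplit:
    pairs = dedup_pairs(pairs)
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(pairs))
    r_train, r_val, _ = spec.transductive_ratios
    n = len(pairs)
    n_train = int(n * r_train)
    n_val = int(n * r_val)
    if n_train == 0 or n_val == 0 or n - n_train - n_val == 0:
        raise SplitError(f"{n} pairs are too few for ratios {spec.transductive_ratios}")
    train = [pairs[i] for i in order[:n_train]]
    val = [pairs[i] for i in order[n_train:n_train + n_val]]
    test = [pairs[i] for i in order[n_train + n_val:]]
    n_known = int(len(train) * spec.known_fraction)
    known_idx = rng.permutation(len(train))[:n_known]
    known = [train[i] for i in sorted(known_idx)]
    return TransductiveSplit(known=known, train=train, val=val, test=test)


def split_inductive(pairs: list[Pair], spec: SplitSpec) -> InductiveSplit:
    pairs = dedup_pairs(pairs)
    genes = sorted({g for pair in pairs for g in pair})
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(len(genes))
    n_train_genes = int(len(genes) * spec.inductive_gene_ratio)
    train_genes = {genes[i] for i in order[:n_train_genes]}
    test_genes = {genes[i] for i in order[n_train_genes:]}

    train_side = [p for p in pairs if p[0] in train_genes and p[1] in train_genes]
    test_side = [p for p in pairs if p[0] in test_genes and p[1] in test_genes]
    n_dropped = len(pairs) - len(train_side) - len(test_side)

    rk, rt, _ = spec.inductive_train_ratios
    perm = rng.permutation(len(train_side))
    n_k = int(len(train_side) * rk)
    n_t = int(len(train_side) * rt)
    known_train = [train_side[i] for i in perm[:n_k]]
    train = [train_side[i] for i in perm[n_k:n_k + n_t]]
    val = [train_side[i] for i in perm[n_k + n_t:]]

    rk_test, _ = spec.inductive_test_ratios
    perm_t = rng.permutation(len(test_side))
    n_k_test = int(len(test_side) * rk_test)
    known_test = [test_side[i] for i in perm_t[:n_k_test]]
    test = [test_side[i] for i in perm_t[n_k_test:]]

    if not (known_train and train and val and known_test and test):
        raise SplitError("too few pairs for the inductive ratios (an output is empty)")
    return InductiveSplit(
        train_genes=train_genes,
        test_genes=test_genes,
        known_train=known_train,
        train=train,
        val=val,
        known_test=known_test,
        test=test,
        n_dropped_cross=n_dropped,
    )


def induced_subkg(kg: HeteroGraph, remove_genes: set[str]) -> HeteroGraph:
    """Drop the given gene entities and all their incident triples.

    The entity table (and its indexing) is preserved; only triples touching
    a removed gene disappear, so the two inductive sub-KGs live in the same
    index space while sharing no gene.
    """
    remove_idx = {kg.entities.index_of(g) for g in remove_genes if g in kg.entities}
    keep = [
        (int(h), int(r), int(t))
        for h, r, t in kg.triples_array()
        if int(h) not in remove_idx and int(t) not in remove_idx
    ]
    relations = [Relation(r.name, r.index, r.is_inverse, r.is_identity, r.inverse_of)
                 for r in kg.relations]
    return HeteroGraph(kg.entities, relations, keep, sl_relation=kg.sl_relation,
                       augmented=kg.augmented)


def both_orientations(pairs: list[Pair]) -> list[Pair]:
    """Expand undirected pairs into both (u, v) and (v, u) supervision queries."""
    out: list[Pair] = []
    for u, v in pairs:
        out.append((u, v))
        out.append((v, u))
    return out
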