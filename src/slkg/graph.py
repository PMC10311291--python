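"""Heterogeneous graph store for synthetic-lethality reasoning.

The working object is a directed heterogeneous graph built from two sources:
a knowledge graph of gene/function triples (head, relation, tail) and an
undirected synthetic-lethality (SL) interaction graph whose pairs are merged
in as bidirectional edges of a dedicated SL relation.  Before reasoning, the
graph is augmented with inverse relations (one ``<name>_inv`` partner per
directed relation) and a shared identity self-loop relation so that entities
reached in fewer than K hops persist through all K message-passing layers.

Entity and relation indices are dense integers assigned by lexicographic
sort of the external identifiers, which makes every downstream computation
reproducible across loads of the same files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SL_RELATION = "SL_GsG"
IDENTITY_RELATION = "identity"
INVERSE_SUFFIX = "_inv"
ENTITY_TYPES = ("Gene", "Pathway", "BP", "MF", "CC")


class GraphError(ValueError):
    """Raised for malformed inputs or contract violations in graph construction."""


@dataclass
class Relation:
    name: str
    index: int
    is_inverse: bool = False
    is_identity: bool = False
    inverse_of: int | None = None


@dataclass
class EntityTable:
    """Dense-indexed entity catalogue with type labels and optional descriptions."""

    ids: list[str] = field(default_factory=list)
    types: list[str] = field(default_factory=list)
    descriptions: list[str] = field(default_factory=list)
    _index: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self._index

    def index_of(self, entity_id: str) -> int:
        try:
            return self._index[entity_id]
        except KeyError:
            raise GraphError(f"unknown entity {entity_id!r}") from None

    def add(self, entity_id: str, entity_type: str = "Gene", description: str = "") -> int:
        if entity_id in self._index:
            return self._index[entity_id]
        idx = len(self.ids)
        self.ids.append(entity_id)
        self.types.append(entity_type)
        self.descriptions.append(description)
        self._index[entity_id] = idx
        return idx

    def gene_indices(self) -> np.ndarray:
        return np.asarray(
            [i for i, t in enumerate(self.types) if t == "Gene"], dtype=np.int64
        )

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, str]]) -> "EntityTable":
        """Build a table with indices assigned by lexicographic sort of IDs."""
        rows = {}
        for entity_id, entity_type, desc in records:
            rows.setdefault(entity_id, (entity_type, desc))
        table = cls()
        for entity_id in sorted(rows):
            entity_type, desc = rows[entity_id]
            table.add(entity_id, entity_type, desc)
        return table


def read_entity_table(path) -> EntityTable:
    """Read TSV ``id<TAB>type[<TAB>description]`` into an :class:`EntityTable`."""
    records = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) == 2:
                entity_id, entity_type = parts
                desc = ""
            elif len(parts) == 3:
                entity_id, entity_type, desc = parts
            else:
                raise GraphError(
                    f"{path}: line {lineno}: expected 2 or 3 columns, got {len(parts)}"
                )
            records.append((entity_id, entity_type, desc))
    return EntityTable.from_records(records)


def read_triple_rows(path, header: bool = False) -> list[tuple[str, str, str]]:
    """Read a 3-column TSV of head/relation/tail string rows (duplicates kept)."""
    rows: list[tuple[str, str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue  # tolerate blank (e.g. trailing) lines
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphError(
                    f"{path}: line {lineno}: expected 3 columns, got {len(parts)}"
                )
            rows.append((parts[0], parts[1], parts[2]))
    return rows


def read_pair_rows(path, header: bool = False) -> list[tuple[str, str]]:
    """Read a 2-column TSV of undirected gene-ID pairs."""
    pairs: list[tuple[str, str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if header and lineno == 1:
                continue
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise GraphError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            pairs.append((parts[0], parts[1]))
    return pairs


class HeteroGraph:
    """Directed heterogeneous graph with CSR-style outgoing adjacency.

    Triples are stored as three parallel int64 arrays (``head``, ``rel``,
    ``tail``) sorted by ``(head, rel, tail)``; ``_head_ptr`` gives the CSR
    row pointers so :meth:`outgoing` is a slice.
    """

    def __init__(
        self,
        entities: EntityTable,
        relations: list[Relation],
        triples: Sequence[tuple[int, int, int]],
        sl_relation: int | None = None,
        augmented: bool = False,
    ):
        self.entities = entities
        self.relations = relations
        self.sl_relation = sl_relation
        self.augmented = augmented
        self.identity_relation: int | None = None
        for r in relations:
            if r.is_identity:
                self.identity_relation = r.index
        self._set_triples(triples)

    # -- construction -----------------------------------------------------

    def _set_triples(self, triples: Sequence[tuple[int, int, int]]) -> None:
        arr = np.asarray(sorted(set(map(tuple, triples))), dtype=np.int64)
        if arr.size == 0:
            arr = np.empty((0, 3), dtype=np.int64)
        self.head = arr[:, 0] if len(arr) else np.empty(0, dtype=np.int64)
        self.rel = arr[:, 1] if len(arr) else np.empty(0, dtype=np.int64)
        self.tail = arr[:, 2] if len(arr) else np.empty(0, dtype=np.int64)
        n = len(self.entities)
        counts = np.bincount(self.head, minlength=n) if len(arr) else np.zeros(n, dtype=np.int64)
        self._head_ptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)

    @property
    def n_triples(self) -> int:
        return len(self.head)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    def relation_index(self, name: str) -> int:
        for r in self.relations:
            if r.name == name:
                return r.index
        raise GraphError(f"unknown relation {name!r}")

    def relation_names(self) -> list[str]:
        return [r.name for r in self.relations]

    # -- queries ----------------------------------------------------------

    def outgoing(self, e: int) -> np.ndarray:
        """All triples with head ``e`` as an (m, 3) array ordered by (rel, tail)."""
        if not 0 <= e < len(self.entities):
            raise GraphError(f"entity index {e} out of range")
        lo, hi = self._head_ptr[e], self._head_ptr[e + 1]
        out = np.empty((hi - lo, 3), dtype=np.int64)
        out[:, 0] = self.head[lo:hi]
        out[:, 1] = self.rel[lo:hi]
        out[:, 2] = self.tail[lo:hi]
        return out

    def outgoing_slice(self, e: int) -> tuple[int, int]:
        return int(self._head_ptr[e]), int(self._head_ptr[e + 1])

    def triples_array(self) -> np.ndarray:
        return np.stack([self.head, self.rel, self.tail], axis=1)

    def sl_pairs(self) -> set[tuple[int, int]]:
        """Undirected SL pairs currently present as edges."""
        if self.sl_relation is None:
            return set()
        mask = self.rel == self.sl_relation
        return {
            (min(h, t), max(h, t))
            for h, t in zip(self.head[mask], self.tail[mask])
        }


def load_triples(
    rows: Sequence[tuple[str, str, str]], entities: EntityTable | None = None
) -> tuple[list[tuple[int, int, int]], EntityTable, list[Relation]]:
    """Index string triples densely; auto-extends the entity table.

    New entities absent from ``entities`` are appended in lexicographic order
    (type defaults to ``Gene`` only when the ID never appears as a relation
    target of an annotation — callers supply metadata when types matter).
    Relations are indexed by lexicographic sort of their names.
    """
    entities = entities if entities is not None else EntityTable()
    unknown = sorted(
        {h for h, _, _ in rows if h not in entities}
        | {t for _, _, t in rows if t not in entities}
    )
    for entity_id in unknown:
        entities.add(entity_id, "Gene", "")
    rel_names = sorted({r for _, r, _ in rows})
    relations = [Relation(name, i) for i, name in enumerate(rel_names)]
    rel_index = {name: i for i, name in enumerate(rel_names)}
    triples = [
        (entities.index_of(h), rel_index[r], entities.index_of(t)) for h, r, t in rows
    ]
    return triples, entities, relations


def build_graph(
    triple_rows: Sequence[tuple[str, str, str]],
    entities: EntityTable | None = None,
) -> HeteroGraph:
    """Build an unaugmented graph from string triple rows (duplicates collapsed)."""
    triples, entities, relations = load_triples(triple_rows, entities)
    return HeteroGraph(entities, relations, triples)


def merge_sl_graph(kg: HeteroGraph, sl_pairs: Iterable[tuple[str, str]]) -> HeteroGraph:
    """Merge undirected SL pairs into ``kg`` as bidirectional SL edges.

    Each pair (u, v) contributes both (u, SL, v) and (v, SL, u) exactly once;
    duplicates collapse, self-pairs are rejected with a warning.  Gene IDs not
    yet in the entity table are created as ``Gene`` entities (appended after
    existing indices, in sorted order).
    """
    entities = kg.entities
    new_genes = sorted(
        {g for pair in sl_pairs for g in pair if g not in entities}
    )
    for g in new_genes:
        entities.add(g, "Gene", "")

    relations = [Relation(r.name, r.index, r.is_inverse, r.is_identity, r.inverse_of)
                 for r in kg.relations]
    names = {r.name for r in relations}
    if SL_RELATION in names:
        sl_idx = kg.relation_index(SL_RELATION)
    else:
        sl_idx = len(relations)
        relations.append(Relation(SL_RELATION, sl_idx))

    triples = [tuple(t) for t in kg.triples_array()]
    for u, v in sl_pairs:
        if u == v:
            warnings.warn(f"self SL pair ({u},{u}) rejected", stacklevel=2)
            continue
        ui, vi = entities.index_of(u), entities.index_of(v)
        triples.append((ui, sl_idx, vi))
        triples.append((vi, sl_idx, ui))
    return HeteroGraph(entities, relations, triples, sl_relation=sl_idx)


def augment(graph: HeteroGraph) -> HeteroGraph:
    """Add inverse relations and identity self-loops.

    Every non-SL relation r gains a partner ``r_inv`` and for each triple
    (h, r, t) the triple (t, r_inv, h) is added.  The SL relation is treated
    as its own inverse (its pairs are already bidirectional), so no SL_inv
    relation is created.  Every entity gains one identity self-loop under a
    single shared ``identity`` relation.
    """
    if graph.augmented:
        raise GraphError("graph is already augmented")
    relations = [Relation(r.name, r.index, r.is_inverse, r.is_identity, r.inverse_of)
                 for r in graph.relations]
    inv_of: dict[int, int] = {}
    for r in list(relations):
        if r.index == graph.sl_relation:
            r.inverse_of = r.index  # SL is self-inverse
            continue
        inv_idx = len(relations)
        relations.append(
            Relation(r.name + INVERSE_SUFFIX, inv_idx, is_inverse=True, inverse_of=r.index)
        )
        r.inverse_of = inv_idx
        inv_of[r.index] = inv_idx
    identity_idx = len(relations)
    relations.append(
        Relation(IDENTITY_RELATION, identity_idx, is_identity=True, inverse_of=identity_idx)
    )

    triples = [tuple(t) for t in graph.triples_array()]
    for h, r, t in graph.triples_array():
        if r in inv_of:
            triples.append((int(t), inv_of[int(r)], int(h)))
    for e in range(len(graph.entities)):
        triples.append((e, identity_idx, e))
    out = HeteroGraph(
        graph.entities, relations, triples,
        sl_relation=graph.sl_relation, augmented=True,
    )
    out.identity_relation = identity_idx
    return out


def write_triples(graph: HeteroGraph, path) -> None:
    """Write the triple list back to 3-column TSV using external IDs."""
    ids = graph.entities.ids
    names = graph.relation_names()
    with open(path, "wt", encoding="utf-8") as fh:
        for h, r, t in graph.triples_array():
            fh.write(f"{ids[h]}\t{names[r]}\t{ids[t]}\n")


def entity_frame(graph: HeteroGraph) -> pd.DataFrame:
    """Entity table as a DataFrame (id, type, description)."""
    return pd.DataFrame(
        {
            "id": graph.entities.ids,
            "type": graph.entities.types,
            "description": graph.entities.descriptions,
        }
    )
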