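"""Desk-scale synthetic heterogeneous graphs with a planted SL rule.

The generator emulates the shape of a gene/function knowledge graph — genes
annotated to function entities (biological processes, molecular functions,
cellular components, pathways) with a heavy-tailed annotation count, plus a
thin layer of function-to-function edges — and plants a three-hop relational
rule for synthetic lethality:

    g_q --SL--> g' --involved_in--> f --involved_in_inv--> g_p

i.e. a gene is an SL partner of g_q if it shares a function entity with one
of g_q's known SL partners.  Starting from random seed pairs, extra pairs
satisfying the rule are derived (each with a recorded support path), and a
fraction of noise pairs is added, rejection-sampled so that no schema path
of the rule exists for them in either orientation — genuinely rule-free
labels.  Everything is seeded, and outputs are loadable by the graph store
without modification.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .encoder import TextEmbeddingTable
from .graph import SL_RELATION, EntityTable, HeteroGraph, augment, build_graph, merge_sl_graph
from .splits import SplitSpec, TransductiveSplit, dedup_pairs, split_transductive

INVOLVED_IN = "involved_in"
PART_OF = "part_of"
RULE_SCHEMA = f"{SL_RELATION}/{INVOLVED_IN}/{INVOLVED_IN}_inv"

Pair = tuple[str, str]


class SimulationError(ValueError):
    pass


@dataclass
class SimConfig:
    n_genes: int = 200
    n_functions: int = 60
    function_type_fractions: tuple[float, float, float, float] = (0.4, 0.2, 0.2, 0.2)
    annotations_per_gene: float = 1.2  # mean of the truncated geometric count
    function_hierarchy_edges: int = 40
    n_seed_sl: int = 60
    derived_per_seed: int = 2  # rule partners derived per seed-pair orientation
    noise_sl_fraction: float = 0.1
    text_dim: int = 32
    seed: int = 0


@dataclass
class SimOutput:
    config: SimConfig
    entities: list[tuple[str, str, str]]  # (id, type, description)
    kg_triples: list[tuple[str, str, str]]
    sl_pairs: list[Pair]
    labels: dict[Pair, str]  # "seed" | "rule" | "noise"
    support_paths: dict[Pair, list[tuple[str, str, str]]]
    annotations: dict[str, set[str]] = field(default_factory=dict)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "entities.tsv", "wt", encoding="utf-8") as fh:
            for eid, etype, desc in self.entities:
                fh.write(f"{eid}\t{etype}\t{desc}\n")
        with open(outdir / "kg_triples.tsv", "wt", encoding="utf-8") as fh:
            for h, r, t in self.kg_triples:
                fh.write(f"{h}\t{r}\t{t}\n")
        with open(outdir / "sl_pairs.tsv", "wt", encoding="utf-8") as fh:
            for u, v in self.sl_pairs:
                fh.write(f"{u}\t{v}\n")
        manifest = {
            "config": asdict(self.config),
            "labels": {f"{u}|{v}": lab for (u, v), lab in self.labels.items()},
            "rule_schema": RULE_SCHEMA,
            "n_sl_pairs": len(self.sl_pairs),
        }
        with open(outdir / "manifest.json", "wt", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)


def _has_schema_support(q: str, p: str, partners: dict[str, set[str]],
                        annotations: dict[str, set[str]]) -> bool:
    """True iff a path q -SL-> g' -involved_in-> f -involved_in_inv-> p exists."""
    for g in partners.get(q, ()):  # g' is a partner of q other than p itself
        if g != p and annotations.get(g, set()) & annotations.get(p, set()):
            return True
    return False


def simulate(config: SimConfig) -> SimOutput:
    """Generate a planted-rule heterogeneous graph (fully seeded)."""
    if config.n_genes < 4 or config.n_functions < 2:
        raise SimulationError("need at least 4 genes and 2 functions")
    if not 0 <= config.noise_sl_fraction < 1:
        raise SimulationError("noise_sl_fraction must be in [0, 1)")
    rng = np.random.default_rng(config.seed)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    type_names = ("BP", "MF", "CC", "Pathway")
    counts = np.floor(
        np.asarray(config.function_type_fractions) * config.n_functions
    ).astype(int)
    counts[0] += config.n_functions - counts.sum()
    functions, ftypes = [], {}
    for tname, c in zip(type_names, counts):
        for i in range(c):
            fid = f"{tname}{i:03d}"
            functions.append(fid)
            ftypes[fid] = tname

    # heavy-tailed annotation counts: truncated geometric with the stated mean
    p_geom = min(1.0, 1.0 / config.annotations_per_gene)
    annotations: dict[str, set[str]] = {}
    kg_triples: list[tuple[str, str, str]] = []
    for g in genes:
        k = int(min(rng.geometric(p_geom), len(functions)))
        chosen = rng.choice(len(functions), size=k, replace=False)
        annotations[g] = {functions[i] for i in chosen}
        for i in sorted(chosen):
            kg_triples.append((g, INVOLVED_IN, functions[i]))

    n_hier = min(config.function_hierarchy_edges,
                 len(functions) * (len(functions) - 1))
    seen_h: set[tuple[int, int]] = set()
    while len(seen_h) < n_hier:
        a, b = rng.choice(len(functions), size=2, replace=False)
        seen_h.add((int(a), int(b)))
    for a, b in sorted(seen_h):
        kg_triples.append((functions[a], PART_OF, functions[b]))

    # seed SL pairs
    sl: dict[Pair, str] = {}
    partners: dict[str, set[str]] = {}

    def add_pair(u: str, v: str, label: str) -> Pair:
        key = (u, v) if u <= v else (v, u)
        sl[key] = label
        partners.setdefault(u, set()).add(v)
        partners.setdefault(v, set()).add(u)
        return key

    while sum(1 for lab in sl.values() if lab == "seed") < config.n_seed_sl:
        a, b = rng.choice(config.n_genes, size=2, replace=False)
        u, v = genes[int(a)], genes[int(b)]
        if (min(u, v), max(u, v)) not in sl:
            add_pair(u, v, "seed")

    # grow the rule closure: for each seed orientation, derive partners that
    # share a function with the known partner
    support_paths: dict[Pair, list[tuple[str, str, str]]] = {}
    seeds = sorted(k for k, lab in sl.items() if lab == "seed")
    gene_by_function: dict[str, set[str]] = {}
    for g, fs in annotations.items():
        for f in fs:
            gene_by_function.setdefault(f, set()).add(g)
    n_derived = 0
    for u, v in seeds:
        for q, w in ((u, v), (v, u)):  # q keeps partner w; derive new partners of q
            cands = sorted(
                {c for f in annotations[w] for c in gene_by_function.get(f, ())}
                - {q, w} - partners.get(q, set())
            )
            if not cands:
                continue
            take = rng.choice(len(cands), size=min(config.derived_per_seed, len(cands)),
                              replace=False)
            for i in sorted(take):
                c = cands[i]
                key = add_pair(q, c, "rule")
                shared = sorted(annotations[w] & annotations[c])[0]
                support_paths[key] = [
                    (q, SL_RELATION, w),
                    (w, INVOLVED_IN, shared),
                    (shared, f"{INVOLVED_IN}_inv", c),
                ]
                n_derived += 1
    if n_derived == 0:
        raise SimulationError(
            "rule closure is empty: annotations too sparse; raise "
            "annotations_per_gene or n_seed_sl"
        )

    # noise pairs with no schema support in either orientation
    n_rule_like = len(sl)
    n_noise = int(round(config.noise_sl_fraction / (1.0 - config.noise_sl_fraction)
                        * n_rule_like))
    attempts = 0
    noise_keys: list[Pair] = []
    while len(noise_keys) < n_noise and attempts < 200 * max(n_noise, 1):
        attempts += 1
        a, b = rng.choice(config.n_genes, size=2, replace=False)
        u, v = genes[int(a)], genes[int(b)]
        key = (min(u, v), max(u, v))
        if key in sl:
            continue
        if _has_schema_support(u, v, partners, annotations) or \
           _has_schema_support(v, u, partners, annotations):
            continue
        add_pair(u, v, "noise")
        noise_keys.append(key)
    if len(noise_keys) < n_noise:
        warnings.warn(
            f"only {len(noise_keys)}/{n_noise} rule-free noise pairs found",
            stacklevel=2,
        )
    # adding SL edges can create support for earlier noise pairs; drop violators
    changed = True
    while changed:
        changed = False
        for key in list(noise_keys):
            u, v = key
            if _has_schema_support(u, v, partners, annotations) or \
               _has_schema_support(v, u, partners, annotations):
                del sl[key]
                partners[u].discard(v)
                partners[v].discard(u)
                noise_keys.remove(key)
                changed = True

    entities = [(g, "Gene", f"synthetic gene {g}") for g in genes] + [
        (f, ftypes[f], f"synthetic function {f}") for f in functions
    ]
    return SimOutput(
        config=config,
        entities=entities,
        kg_triples=kg_triples,
        sl_pairs=sorted(sl),
        labels=dict(sl),
        support_paths=support_paths,
        annotations=annotations,
    )


def sim_graph(sim: SimOutput, known_pairs: list[Pair] | None = None) -> HeteroGraph:
    """Build the augmented message graph: KG plus (known) SL pairs."""
    table = EntityTable.from_records(sim.entities)
    kg = build_graph(sim.kg_triples, table)
    pairs = sim.sl_pairs if known_pairs is None else known_pairs
    return augment(merge_sl_graph(kg, pairs))


def make_text_table(sim: SimOutput, graph: HeteroGraph) -> TextEmbeddingTable:
    """Seeded synthetic text embeddings keyed by entity index."""
    return TextEmbeddingTable.synthetic(
        len(graph.entities), d_text=sim.config.text_dim, seed=sim.config.seed + 1
    )


@dataclass
class HoldoutResult:
    split: TransductiveSplit
    graph: HeteroGraph  # augmented message graph (KG + known SL pairs)
    solvable: dict[Pair, bool]  # oriented (primary, partner) -> rule support exists

    def solvable_oriented(self) -> list[Pair]:
        return [k for k, ok in self.solvable.items() if ok]


def rule_holdout(sim: SimOutput, spec: SplitSpec) -> HoldoutResult:
    """Split the simulated SL pairs and flag held-out pairs solvable by the rule.

    An oriented held-out pair (q, p) is solvable when the message graph
    (KG + known SL edges) contains at least one schema path
    q -SL-> g' -involved_in-> f -involved_in_inv-> p through a *known*
    partner g' of q.
    """
    split = split_transductive(sim.sl_pairs, spec)
    graph = sim_graph(sim, split.known)
    known_partners: dict[str, set[str]] = {}
    for u, v in split.known:
        known_partners.setdefault(u, set()).add(v)
        known_partners.setdefault(v, set()).add(u)
    solvable: dict[Pair, bool] = {}
    for u, v in split.test:
        for q, p in ((u, v), (v, u)):
            solvable[(q, p)] = _has_schema_support(q, p, known_partners, sim.annotations)
    return HoldoutResult(split=split, graph=graph, solvable=solvable)
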