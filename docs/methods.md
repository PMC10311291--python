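# Methods

## The prediction problem

Synthetic lethality (SL) is a genetic interaction in which inhibiting either
of two genes alone leaves a cell viable while inhibiting both kills it.
Given a *primary* gene g_q, the package ranks every other gene in a
vocabulary V as a candidate SL partner.  Inputs are (i) a set of known
undirected SL pairs and (ii) a knowledge graph (KG) of directed triples
(head, relation, tail) over typed entities — genes, pathways and GO terms
(biological process, molecular function, cellular component).  The two are
merged into one directed heterogeneous graph: each SL pair becomes a pair of
directed edges of a dedicated relation (`SL_GsG`), every relation gains an
inverse partner (`<name>_inv`), and every entity gains an identity self-loop
under a single shared relation.  Identity loops let an entity reached after
fewer than K hops persist to the last layer, so genes closer than K hops
remain scorable.

## Relational digraphs

A relational path of length K is a chain of K triples from g_q to a
candidate.  For one primary gene, the union of all K-hop relational digraphs
is built once by layer-wise frontier expansion: frontier 0 is {g_q}; layer k
collects every outgoing triple of frontier k−1 and the distinct destinations
form frontier k.  Each graph edge is touched at most K times, and the
digraph for any specific pair (g_q, g_p) is recovered by a backward sweep
from g_p — no per-pair subgraph extraction.  A brute-force K-walk enumerator
(exponential, budget-guarded at 10^6 walks) serves as an independent oracle:
on random graphs the backward slice equals the union of enumerated path
triples exactly.

## Encoder

At layer k, for an edge (e_i, r, e_o) between frontiers, with row-vector
convention x W:

* message: m = (h_{e_i}^{k−1} + rel_k[r] + P T_{e_i} + P T_{e_o}) W1_k,
  where T are per-entity text embeddings and P a learned projection to the
  latent width d.  Without a text table the two projection terms vanish
  (the structure-only variant).
* gate: α = sigmoid( watt1_kᵀ · ReLU(m Watt2_k) ), an independent per-edge
  sigmoid in (0, 1) — not softmax-normalized across edges.
* aggregation: z_{e_o} = act( (Σ_edges α·m) W2_k ), act = ReLU by default.
* recurrent update: a GRU combines z with the entity's layer-(k−1) state
  (zero if the entity was absent from the previous frontier):
  r = σ(zWr + h'Ur + br), f = σ(zWf + h'Uf + bf),
  n = cand(zWn + r∗(h'Un) + bn), h = (1−f)∗n + f∗h'.

The query gene starts from the zero vector; the query is identified
structurally as the digraph root.  Relation embeddings are per-layer tables.
Dropout (default 0.5) is applied to z before the recurrent update, only
during training.

Numerical/config choices:

* The gate inside the candidate term n is written with σ throughout the
  model equations, so the candidate activation defaults to sigmoid; tanh is
  available via `gru_candidate_activation` (the conventional GRU choice,
  and the two differ by well under the training noise here).
* The aggregation activation defaults to ReLU (`agg_activation`), pairing
  with the ReLU inside the gate.
* **Open-gate initialization.** The gate readout watt1 is initialized
  half-normal at scale 2 (entries |N(0,1)|·2), so every edge gate starts
  high and training selectively closes uninformative edges.  With a
  symmetric initialization the gates start scattered around 0.5 and half of
  them nearly shut; a small run's few optimizer steps cannot reopen a shut
  gate on an informative edge, which destroys threshold-based explanation
  extraction while barely affecting ranking (the gate's overall scale can be
  absorbed by the downstream linear maps).  This mirrors the LSTM
  forget-bias warm start.  All other matrices are Xavier-uniform; relation
  embeddings are N(0, 1/√d); biases start at zero.

## Scoring and loss

A gene g_p on the last frontier scores s(g_q, g_p) = W_ffᵀ h_{g_q,g_p}^K +
b_ff; every gene of V not on the last frontier scores exactly zero.  Each
candidate gene is treated as a class: the loss is cross-entropy of each
supervised partner under a softmax over all genes in V (unreached genes
participate with their pinned zero score).  A config switch
(`loss_candidates="positives"`) restricts the normalizer to the primary's
own training partners — the narrower literal reading of the loss notation —
but it performs far worse (it carries no signal about negatives) and is off
by default.

**Pair-specific leakage masking.** When a supervised pair (g_q, g_p) is
scored during training, the direct edges g_q↔g_p of the SL relation are
removed from that forward pass's digraph; otherwise a retained direct edge
yields a trivial 3-hop shortcut (SL, identity, identity).  The mask is
per-pair, not per-primary: masking the primary's edges to *all* its
positives at once would also delete the first hop of the genuine multi-hop
support (g_q →SL→ partner →involved_in→ term →involved_in_inv→ g_p),
because known partners are themselves supervision positives.  With the
grouped mask the model cannot see the structure it is supposed to learn and
ranking degrades to weak correlates; the per-pair mask is what makes the
planted-rule experiment (below) succeed.

## Training

Adam with classic L2 regularization folded into the gradient.  Defaults
follow the stated conditions: K = 3 layers, d = 48, batches of 50 distinct
primary genes (all their positives included; one optimizer step per batch),
dropout 0.5, at most 50 epochs.  The learning rate and weight decay default
to midpoints of the tuning ranges [1e-4, 1e-3] and [1e-5, 1e-3]; the
scaled-down study below selects lr = 1e-3, weight decay = 1e-5 on
validation NDCG@10, which is also the model-selection metric: the epoch
with the best validation NDCG@10 is kept.  Every stochastic choice (splits,
initialization, batch order, dropout, neighbor sampling) derives from the
single run seed.  The differentiable graph is built on a small reverse-mode
autodiff core over numpy (`slkg.autodiff`) whose primitives are verified
against central finite differences.

## Splits

Transductive: undirected pairs split 7:1:2 into train/validation/test; 60%
of the training pairs become "known" pairs, which are the only SL edges in
the message graph.  Inductive: SL genes split 6:4 into disjoint train/test
sets with sub-KGs induced by dropping the other side's gene entities;
train-side pairs split 4:3:3 (known : supervision : validation), test-side
4:6 (known : test); pairs straddling the partition are dropped and counted.
Supervision pairs are expanded to both orientations.  Evaluation is
filtered top-N ranking: for each test primary, its known/train/validation
partners and itself are removed, candidates sort by (score desc, gene index
asc), and NDCG@N / Precision@N / Recall@N (binary relevance, log-2
discount, ideal DCG truncated at min(|relevant|, N)) are macro-averaged
over primaries.  Precision uses denominator N by default;
`precision_denominator="min"` gives the variant with denominator
min(N, |relevant|), under which Precision@N equals Recall@N whenever all
relevant items fit in the list.

## Explanation extraction

For a predicted pair, attention weights recorded during the (dropout-free)
scoring pass are projected onto the pair's backward-sliced digraph.  Layers
1..K−1 keep edges with α above a threshold (default 0.9); at the last layer
the five highest-α edges are kept, ranked within the pool of edges whose
source is reachable through the kept earlier layers — the reading under
which the kept last-layer edges can actually complete root-to-partner paths
(`last_layer_pool="slice"` ranks all last-layer edges instead).  Only edges
on complete paths remain; each path is summarized by its schema signature,
the "/"-joined relation-name sequence, which acts as the inference rule the
model applied.

## Synthetic data with a planted rule

The generator emulates a gene/function KG: `n_genes` genes annotated to
`n_functions` function entities (BP/MF/CC/Pathway in a 4:2:2:2 split) via
`involved_in`, a thin `part_of` layer among functions, and SL pairs planted
by the three-hop rule *g_q is SL with g_p if a known partner of g_q shares a
function with g_p* (`SL_GsG/involved_in/involved_in_inv`).  Random seed
pairs are drawn, rule pairs are derived from them (each with a recorded,
oracle-verified support path), and a `noise_sl_fraction` of extra pairs is
rejection-sampled to have **no** schema path in either orientation —
genuinely rule-free labels.

Annotation counts are truncated-geometric (heavy-tailed).  The default mean
is 1.2 annotations per gene: identifiability of the planted rule dictates
this density.  Two random genes with m annotations each over F functions
share one with probability ≈ 1 − (1 − m/F)^m, so with F = 60 a mean of 5
annotations makes roughly a third of all gene pairs "rule candidates" —
per query the rule set is of order a hundred genes, and no ranker, not
even an oracle that knows the rule exactly, can place 1–2 relevant
partners in a top-10 drawn from it (Recall@10 ceiling ≈ 10/|rule set|).
At mean 1.2 the sharing probability drops to ~2%, the rule set to under
ten genes, and the ceiling close to 1, leaving the experiment able to
distinguish a model that learned the rule from one that did not.
`rule_holdout` splits the pairs transductively and flags each oriented
held-out pair *solvable* if the message graph retains at least one schema
path through a known partner; metrics for the study are computed on
solvable pairs, since unsolvable ones are unanswerable in principle.

What the generator does not emulate: real GO DAG topology, realistic degree
distributions beyond heavy-tailedness, meaningful entity text (synthetic
text embeddings are seeded unit Gaussians and carry identity, not
semantics), or cell-line context.  Passing the study therefore shows the
machinery recovers a multi-hop relational rule at desk scale — not that it
reproduces performance on real SL databases.

## The scaled-down study

`scripts/acceptance.py` (and the corresponding tests) runs: 200 genes, 60
functions, 60 seed pairs, noise fraction 0.1, simulation/split seed 7;
K = 3, d = 48, batch 50, dropout 0.5, ≤30 epochs, lr 1e-3, weight decay
1e-5 on one CPU (about a minute of training).  It reports trained Recall@10
on solvable held-out pairs against two floors — a seeded random ranking of
the same filtered candidates (chance) and an untrained random-parameter
model — plus the fraction of correctly top-10-ranked pairs whose extracted
explanation contains the planted schema, and validation NDCG@10 of the full
model versus the no-GRU variant.  Note the untrained-model floor sits well
above analytic chance: even random readouts of the layered representations
correlate with connectivity, and reachability alone (the exact-zero rule
for unreached genes) is informative.  The random-ranking floor is the
correct chance reference.

## Known limitations

* One CPU-bound forward pass per (primary, pair) — fine at desk scale,
  hours at database scale; the design trades speed for exactness (no
  neighbor sampling by default; the `neighbor_sample` option reproduces the
  sampled variants).
* Attention saturation depends on optimizer steps; at very small step
  budgets the 0.9 explanation threshold interacts with the open-gate
  initialization (see above), and thresholds should be read against the
  model's own attention distribution.
* The multi-class loss normalizer over all genes is quadratic-ish in |V|
  per batch through the reached-gene score vectors; |V| in the tens of
  thousands would need a sampled softmax.
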