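# Methods

This note records the models, conventions and design choices behind
`rxngraph`, in the order the data flows: linear notation → graphs → ITS →
rules → rewriting → networks.

## Molecular graphs and the hydrogen convention

Molecules are simple undirected `networkx` graphs. Node attributes are
`element`, `charge`, `hcount` (implicit hydrogens; an explicit H neighbour
is never double-counted), `radical`, `atom_map`, `isotope`; edges carry a
single `order` ∈ {1, 1.5, 2, 3}. Aromatic systems are perceived by RDKit on
parse and carried as order 1.5 everywhere, so kekulé variants of one ring
can never disagree in an isomorphism check and a bond that changes only its
kekulé assignment is not a reaction-center edge.

Hydrogens are implicit except (a) explicit mapped H atoms in the input and
(b) hydrogens that participate in a transformation, which *hydrogen
completion* promotes to explicit nodes before ITS construction. Completion
handles two cases deterministically (donors and acceptors paired lowest map
index first): an implicit hcount difference on a mapped heavy atom creates
a fresh explicit H pair on both sides with a fresh map; an explicit H mapped
on only one side (e.g. `[H:3][H:4]` consumed into C–H bonds) gets its
counterpart materialized on the other side, keeping its map. Species
identity always uses the *hydrogen-collapsed* normal form (plain explicit H
folded back into `hcount`), so explicit/implicit bookkeeping differences
cannot split one species into two.

Agents between the `>` tokens of a reaction SMILES are discarded with a
logged warning; stereochemical tokens are parsed and dropped with a
warning; isotopes ride along as an inert attribute.

## ITS graphs and reaction centers

A balanced record (every atom mapped on both sides, elements agreeing)
merges into one supergraph keyed by atom-map index: each edge stores the
order pair *(o_G, o_H)* with 0 for "absent on that side"; charge, hcount
and radical are stored as (before, after) pairs; `(0,0)` edges are never
stored. Restricting to o_G > 0 (resp. o_H > 0) with before (after) states
reproduces the reactant (product) ensemble — this projection property is
what makes the representation lossless for balanced reactions, and the
reverse direction (`its_to_reaction`) validates chemical writability
through RDKit sanitization.

The radius-0 center is the changed edges plus incident atoms; atoms whose
charge or radical state changes with no bond change are included too (an
outer-sphere electron transfer has a nonempty, edgeless center). Radius-r
expansion measures hops on the union connectivity — an atom visible from
either side's bonding belongs to the environment — and takes the induced
subgraph, so centers are monotone in r with a fixed point at the graph
diameter.

## Canonical identities

`canonical_form` is an individualization–refinement canonicalizer:
equitable-partition refinement (splitting color classes by the multiset of
(edge label, neighbour color) pairs) alternates with branching on each
vertex of the first smallest non-singleton cell; the certificate is the
lexicographic minimum over all branches of the relabeled graph's string
form. Branching is exhaustive with no automorphism pruning — simple and
clearly correct; the cost is exponential only on highly symmetric inputs,
which molecular graphs of the sizes handled here (≤ ~40 nodes, hydrogens
collapsed) do not approach. Initial colors are (label, degree).

`wl_hash` runs k rounds (default 3) of neighbourhood aggregation — node
label ⊕ sorted multiset of (edge label, neighbour label), compressed by a
truncated SHA-256 — and digests the sorted final label multiset; k = 0
digests the raw node-label multiset. Isomorphic graphs always collide
(soundness); the converse fails on the classic 1-WL blind spots (C6 vs
2×C3), which the exact certificate resolves. Edge labels participate
because reaction semantics live on edges (order pairs). Digests are
truncated cryptographic hashes, stable across runs and platforms.

Atom-map canonicalization renumbers reactant atoms 1..N along the exact
canonical ordering of the reactant ensemble and rewrites product maps
through the atom–atom map; the output is idempotent and invariant under
any input renumbering. Atom-map equivalence of two records is defined as
label- and order-pair-preserving isomorphism of their ITS graphs, which
correctly identifies symmetry-equivalent mappings (e.g. swapped hydrogen
targets on a symmetric alkene).

## Matching, SING, clustering

`find_embeddings` is a backtracking monomorphism enumerator (VF2-family):
pattern nodes are ordered along adjacency from a high-degree root, with
label, degree and back-edge consistency pruning; noninduced by default,
induced on request; output order is deterministic. `is_isomorphic` is the
induced search between graphs of equal size/edge count with early label-
and degree-multiset rejection.

The SING-style index stores, per host node, the set of labeled simple-path
signatures up to depth d (default 3). A monomorphism maps every labeled
simple path of the pattern onto an equally labeled simple path of the host
(injectivity preserves simplicity), so any host lacking a pattern feature,
and any host node whose feature set does not contain a pattern node's
feature set, can be discarded without losing embeddings — the filter is
sound, and the backtracking verifier makes results exactly equal to the
naive sweep. Parallel edges are refused; the structure is undirected only.

Clustering buckets graphs by WL digest and links exactly within buckets by
comparing to one representative per cluster (isomorphism is an equivalence
relation, so representative comparison suffices). Soundness of the WL hash
guarantees the prefilter never separates isomorphic graphs, hence the
partition equals exhaustive all-pairs clustering for every iteration count;
batch clustering partitions the input, clusters batches, and merges batch
representatives, again without changing the partition. Representatives are
the first member in deterministic input order; final clusters are sorted by
the representative's exact certificate for stable output. The default
clustering key for reactions is the radius-0 center with node labels
(element, charge pair) and edge labels (order pair).

## Rules, composition

`extract_rule` turns a center (any radius) into a span: *L* is the reactant
projection, *R* the product projection, *K* all nodes plus the unchanged
bonds; node ids are the atom maps; rule ids are content-addressed
(certificate hash), so rule libraries deduplicate for free. Rule nodes
constrain element and charge only — hydrogen counts are deliberately free so
coarse rules generalize, with transformation hydrogens explicit as nodes.
Charge changes live as differing left/right node labels (the minimal
faithful DPO relabeling). Inversion swaps L and R and is an involution.

Composition glues p2's left pattern onto p1's right pattern. Overlaps are
enumerated per connected component of L2: each embeddable component is
overlapped in every distinct way ("as available"); components with no
embedding stay explicit co-reactants. Partial composition adds two options
per component — stay explicit, or be flagged *implicit* (condition-
sourced) — and therefore returns a superset that includes all full
composites; composites are deduplicated by certificate. Implicit atoms are
retained on the rule (mass bookkeeping still balances) but excluded from
matching; the reactor materializes them at application time. Composing a
hydrogenation rule against a substrate identity rule with the H2 component
implicit yields the direct alkene → alkane rule that applies without an
explicit H2 reactant. Because the admissibility condition on overlaps is
enumerated at component granularity, the composite set may be a superset
of formalisms that also glue sub-component overlaps.

## The reactor

Application is standard DPO: enumerate embeddings of the matchable left
pattern (element + charge node compatibility, exact order edge
compatibility), filter by mode, check the dangling condition for deleted
nodes, rewrite, and deduplicate product ensembles by their sorted
canonical certificates (symmetric embeddings yield one result; the
alternative — deduplication by embedding — would report automorphic
variants separately).

*Component-covering* requires the induced map from pattern components to
substrate molecules to be a bijection: every pattern molecule in its own
substrate molecule, every substrate molecule used. This is what blocks a
bimolecular template from firing on two motifs of one molecule;
`unconstrained` mode lifts it for deliberate intramolecular chemistry.
A consequence worth knowing: a rule whose left pattern is disconnected
*within one molecule* (e.g. the inverse of an SN-type ring opening at
radius 0, where the preserved ring path is context, not core) can never
fire under component-covering; such chemistry needs radius ≥ 1 rules or
unconstrained mode. The shipped template library avoids that shape so the
corpus is exactly recoverable at radius 0 in both directions.

Implicit hydrogens are handled by subsumption: if the pattern contains
explicit H nodes, the substrate's implicit hydrogens are promoted to
explicit nodes for the match (a debit from the heavy atom's count), and
product identities are taken on the collapsed form.

Two safeguards bound the combinatorics: `embed_threshold` (default 5000)
hard-caps enumerated embeddings, with a `truncated` flag on the outcome;
`embed_pre_filter` skips a rule/substrate pair when an *admissible
estimate* of the embedding count already exceeds the cap. The estimate is,
per pattern component, the number of label-compatible anchors for the
rarest-label root times the worst-case substrate branching for each
(parent label, order, child label) step of a spanning tree — an upper
bound on tree homomorphisms and hence on embeddings, so the prefilter
never discards a pair whose true count is under the cap.

## MTG construction

Steps are aligned onto the accumulated intermediate by atom-map identity
when the step shares map ids with the mechanism (element disagreement on
shared ids falls back to embedding; state or bond disagreement is a stitch
error — the package refuses to overwrite conflicting trajectories), and
otherwise by component-wise label-preserving embedding of the
hydrogen-collapsed reactant projection into the collapsed intermediate,
first deterministic embedding wins, unmatched components entering as new
species. Hydrogen bookkeeping is reconciled across conventions: a hydrogen
the step holds explicit but the mechanism holds implicit is materialized
retroactively (its history rewritten back to step 0); one the mechanism
holds explicit while the step counts implicitly is treated as a spectator
via a per-atom hcount slack. Atoms entering at step t get vectors padded
with their entry state and a presence flag that is false before entry.
`o[0]` is the pre-mechanism state and `o[t]` the state after step t, so the
slice at t is exactly `(o[t-1], o[t])` restricted to step-t atoms, and the
net is `(o[0], o[n])`. Only linear chains are supported; branching
mechanisms are rejected.

## CRN expansion and route search

Expansion is breadth-first closure: per generation, every rule is applied
component-covering to every substrate multiset of size equal to the rule's
explicit component count, drawn with replacement from the known species
(dimerization allowed); species are deduplicated by collapsed certificate;
rule×multiset combinations are memoized; exceeding the per-generation
hyperedge cap sets a truncation flag rather than losing results silently.
Seeds may be marked *abundant* (reagents like water or acids); expansion
never consumes species, so abundance only documents intent for costing.

Route search is an A*-flavoured best-first relaxation over the hyperedge
structure: seeds cost 0, an edge becomes applicable once all reactants are
settled, a species costs the cheapest `edge_cost + Σ reactant costs`, and
the route is the backtracked derivation tree. The default heuristic is 0
at the target and 1 elsewhere — trivially admissible, so default routes are
step-count minimal (verified against breadth-first search on generated
interconversion networks); a stronger "topological distance" heuristic was
deliberately not asserted because no admissible general chemical heuristic
exists. Custom scorers replace edge costs (the heuristic is clamped to 0),
may return `+inf` to prune, and must be non-negative — a negative cost
raises a contract error. Ties break on the lexicographic species
certificate, making searches deterministic.

## Synthetic data

The corpus generator exists because the package must be testable without
external reaction datasets. It ships 25 hand-written coarse templates
(hydrogenations and additions, cycloadditions and their reverse,
substitutions neutral and ionic, eliminations, carbonyl chemistry,
condensation, isomerizations) whose radius-0 cores are pairwise
non-isomorphic — asserted by a test. A reaction is generated by decorating
a template with a random acyclic C/N/O substituent tree (0–8 heavy atoms,
carbon-rich, valence-legal, no rings so brute-force oracles stay cheap),
attached through the atom map identically on both sides; the radius-0
center of every generated reaction is therefore exactly its template's
core, reactions are balanced by construction, and generation is
byte-reproducible per seed. Decorating the reaction directly (rather than
decorating L and running the rule engine) keeps the generator independent
of the reactor, which the recovery tests then genuinely exercise.

What this corpus does **not** emulate: real corpora contain mapping
errors, unbalanced records, stereochemistry, ring-forming decorations,
tautomer ambiguity, and template distributions that are heavily skewed —
so passing tests here demonstrate algorithmic correctness (exactness of
the prefilter, losslessness, recovery), not robustness to noisy real-world
mapping. Collision rates of the WL hash are corpus-specific and are
deliberately not asserted on synthetic data.

Worked fixtures include the Diels–Alder cycloaddition, the
alkyne/alkene hydrogenation pair, the but-2-ene partial-composition case,
a two-step aldol mechanism (tautomerization, then C–C bond-forming
addition, with the shuttled proton's O–H bond transient), and a
nitrophenol route set in which positional selectivity (para nitration of
chlorobenzene, meta chlorination of nitrobenzene) is encoded as refined
rules whose pattern is the full substrate ring with explicit hydrogens;
hydrolysis is a radius-1 generic aryl-chloride rule. Route feasibility is
*not* modeled — the chemically unreasonable phenol-nitration path exists in
the network precisely so that scorer-based pruning has something to prune.

## Problem sizes and numerics

Validation scales were chosen to run comfortably on one CPU: 500-reaction
corpora from 25 templates for clustering/lossless/recovery checks,
270 patterns × 1,000 hosts for index-vs-naive equivalence, 500 graph pairs
(≤ 10 nodes) against the brute-force all-bijections oracle, 100 random
instances for route optimality. All comparisons are exact (integers or
certificates); the only floating-point quantities are bond orders, drawn
from the fixed set {0, 1, 1.5, 2, 3}, and route costs, which are sums of
user-scorer values. Determinism throughout comes from sorted iteration
orders, content-addressed identifiers, and seeded `random.Random`
instances; no global RNG state is touched.

## Known limitations

- No stereochemistry anywhere (parsed and dropped); distinct stereoisomers
  conflate.
- No resonance or tautomer equivalence beyond input aromatization;
  tautomers compare as different molecules.
- Exact canonicalization has no automorphism pruning; pathological
  symmetric graphs (far beyond molecular sizes) would be slow.
- Component-covering cannot apply single-molecule-disconnected patterns
  (see reactor section); use radius ≥ 1 rules or unconstrained mode.
- MTGs are linear; branching/recursive pathways are rejected with an error.
- Atom maps that overlap across mechanism steps are trusted when elements
  agree; steps that accidentally reuse map ids for different atoms of the
  same element cannot be detected and should be fully renumbered instead.
- The CRN is a closure under the rule library, not a kinetic model; route
  costs are step counts or user scores, not feasibility estimates.
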