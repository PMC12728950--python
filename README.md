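# rxngraph

Graph-based modeling of chemical reactions for cheminformatics and
computer-aided synthesis workflows: reaction canonicalization, template
extraction and clustering, double-pushout (DPO) rewriting, and reaction
network exploration — all on plain `networkx` graphs, with RDKit handling
the SMILES layer.

## Who this is for

Anyone who needs to treat atom-mapped reactions as first-class graph
objects: deduplicating and classifying mapped reaction corpora, extracting
reusable transformation rules, predicting products (forward) or precursors
(backward) with those rules, and searching the reaction network they span.

## The representations

**ITS graph.** A balanced, atom-mapped reaction `G → H` is superposed into a
single *Imaginary Transition State* supergraph: nodes are the mapped atoms,
and every edge carries an order pair *(o<sub>G</sub>, o<sub>H</sub>)* — the
bond order before and after the reaction, with 0 meaning absent. An edge is
*changed* iff o<sub>G</sub> ≠ o<sub>H</sub>; the changed edges plus their
atoms form the **reaction center**, expandable by a bond radius *r* to
capture the local environment. Hydrogens that migrate are promoted to
explicit nodes so the center is exact; spectator hydrogens stay implicit.

**DPO rule.** A reaction template is a span *L ← K → R*: the left pattern
*L*, the preserved context *K*, and the replacement *R*. Applying a rule to
a substrate ensemble means finding a monomorphism *m: L → G*
(*component-covering* by default: pattern molecules map bijectively onto
substrate molecules, which blocks intermolecular templates from firing
intramolecularly), checking the gluing condition, and rewriting. Rules
compose: sequential steps collapse into one composite rule, and *partial*
composition can mark a co-reactant as condition-sourced, yielding e.g. a
hydrogenation rule that applies without an explicit H₂.

**MTG.** An *n*-step mechanism is stitched into a *Mechanistic Transition
Graph*: bonds carry order vectors `o[0..n]`, atoms carry charge/hcount/
radical vectors. Slicing at *t* recovers step *t*'s ITS; collapsing to
`(o[0], o[n])` gives the net reaction, which elides transient features
(a bond with `o[0] = o[n] = 0` but a positive interior entry is *transient*).

**Identity.** Two canonical identities back everything: an exact
individualization–refinement canonicalizer (equal certificates ⇔
isomorphic) and a fast Weisfeiler–Lehman graph hash (sound but incomplete),
used as a clustering prefilter and as the candidate filter of the
SING-style substructure index.

## Worked example

```python
>>> import rxngraph as rg
>>> from rxngraph import graphs as G

>>> its = rg.its_from_smiles(rg.fixtures.DIELS_ALDER)
>>> rg.changed_edges(its)
{(1, 2): (2.0, 1.0), (1, 6): (0.0, 1.0), (2, 3): (1.0, 2.0),
 (3, 4): (2.0, 1.0), (4, 5): (0.0, 1.0), (5, 6): (2.0, 1.0)}
```

Three π bonds become σ/π-shifted (2→1, 1→2) and two new σ bonds form
(0→1): the six-electron cycloaddition core. Extract it as a rule and apply
it to a *different* diene/dienophile pair:

```python
>>> rule = rg.extract_rule(rg.reaction_center(its), rule_id="diels_alder")
>>> sub = G.disjoint_union([rg.parse_smiles("CC=CC=C"), rg.parse_smiles("C=CC#N")])
>>> for res in rg.apply(rule, sub):
...     print(res.product_smiles())
CC1C=CCCC1C#N
CC1C=CCC(C#N)C1
```

The two products are the "ortho" and "meta" regiochemical outcomes of
penta-1,3-diene + acrylonitrile — the engine enumerates every admissible
embedding and deduplicates symmetric ones. Network search, on the packaged
nitrophenol rule set:

```python
>>> seeds, abundant = rg.fixtures.nitrophenol_seeds()
>>> net = rg.expand(seeds, list(rg.fixtures.nitrophenol_rules().values()),
...                 generations=3, abundant=abundant)
>>> route = rg.find_route(net, rg.parse_smiles("Oc1ccc(cc1)[N+](=O)[O-]"))
>>> route.cost, [s.rule_id for s in route.steps]
(3.0, ['chlorination_benzene', 'nitration_para_to_cl', 'hydrolysis_aryl_chloride'])
```

The 12-species network contains both the viable *para* route shown above
and the *meta* byproduct branch (chlorination of nitrobenzene); a scorer
that returns `+inf` for an edge prunes it from the search — no
thermodynamic or kinetic feasibility is modeled.

A `rxngraph` console script exposes the same functionality
(`convert`, `canon`, `center`, `cluster`, `extract`, `compose`, `react`,
`crn`, `route`, `fixtures`); run `rxngraph --help`.

## Scope

No stereochemistry (stereo tokens are parsed and dropped), no resonance or
tautomer equivalence beyond aromatization on input, no yield/selectivity
scoring, no branching mechanisms in MTGs. See `docs/methods.md` for the
model details, numerical conventions, and known limitations.
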