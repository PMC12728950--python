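"""Graph canonicalization and hashing.

Two complementary identities for labeled graphs are provided:

* :func:`canonical_form` -- an exact canonicalizer in the
  individualization--refinement family (Nauty/Bliss style): equitable
  partition refinement alternates with branching on an individualized
  vertex of the first smallest non-singleton cell; the certificate is the
  lexicographic minimum over all branches.  Equal certificates hold *iff*
  the graphs are isomorphic (label- and edge-label-preserving).

* :func:`wl_hash` -- an approximate Weisfeiler--Lehman graph hash:
  ``k`` rounds of neighborhood label aggregation followed by a digest of
  the sorted final label multiset.  Isomorphic graphs always hash equally;
  the converse may fail (1-WL blind spots such as C6 vs 2xC3).

Both accept callables that project a node/edge attribute dict to a hashable
label, so the same machinery serves molecules (element, charge, hcount,
radical / bond order) and ITS graphs (state pairs / order pairs).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from itertools import permutations
from typing import Callable, Hashable, Sequence

import networkx as nx

from . import graphs as G
from .errors import ITSError

NodeLabel = Callable[[dict], Hashable]
EdgeLabel = Callable[[dict], Hashable]


def _default_node_label(d: dict) -> Hashable:
    return d.get("label")


def _default_edge_label(d: dict) -> Hashable:
    return d.get("label")


@dataclass(frozen=True)
class CanonicalForm:
    """Canonical node ordering plus a string certificate of the relabeled graph."""
    ordering: tuple
    certificate: str


@dataclass(frozen=True)
class WLHash:
    iterations: int
    digest: str


# ---------------------------------------------------------------------------
# exact canonicalization
# ---------------------------------------------------------------------------

def _refine(g: nx.Graph, colors: dict, elabel: dict) -> dict:
    """Equitable-partition refinement: split color classes by the multiset of
    (edge label, neighbor color) pairs until the partition is stable."""
    while True:
        keys = {}
        for v in g.nodes:
            sig = tuple(sorted((elabel[frozenset((v, u))], colors[u]) for u in g[v]))
            keys[v] = (colors[v], sig)
        ranked = {k: i for i, k in enumerate(sorted(set(keys.values())))}
        new = {v: ranked[keys[v]] for v in g.nodes}
        if len(set(new.values())) == len(set(colors.values())):
            return new
        colors = new


def _cert_from_discrete(g: nx.Graph, colors: dict, nlabel: dict, elabel: dict) -> tuple[str, tuple]:
    order = sorted(g.nodes, key=lambda v: colors[v])
    pos = {v: i for i, v in enumerate(order)}
    node_part = tuple(repr(nlabel[v]) for v in order)
    edge_part = tuple(sorted((min(pos[u], pos[v]), max(pos[u], pos[v]),
                              repr(elabel[frozenset((u, v))])) for u, v in g.edges))
    return repr((node_part, edge_part)), tuple(order)


def _canon_search(g: nx.Graph, colors: dict, nlabel: dict, elabel: dict) -> tuple[str, tuple]:
    colors = _refine(g, colors, elabel)
    cells: dict[int, list] = {}
    for v in g.nodes:
        cells.setdefault(colors[v], []).append(v)
    target = None
    for c in sorted(cells):
        if len(cells[c]) > 1:
            if target is None or len(cells[c]) < len(cells[target]):
                target = c
    if target is None:
        return _cert_from_discrete(g, colors, nlabel, elabel)
    best: tuple[str, tuple] | None = None
    for v in sorted(cells[target], key=repr):
        # individualize v: split its cell, keep all other cells intact
        branched = {u: (colors[u], 0 if u == v else 1) for u in g.nodes}
        ranked = {k: i for i, k in enumerate(sorted(set(branched.values())))}
        cand = _canon_search(g, {u: ranked[branched[u]] for u in g.nodes}, nlabel, elabel)
        if best is None or cand[0] < best[0]:
            best = cand
    return best


def canonical_form(g: nx.Graph, node_label: NodeLabel = _default_node_label,
                   edge_label: EdgeLabel = _default_edge_label) -> CanonicalForm:
    """Exact canonical form of a simple undirected labeled graph.

    The certificate is invariant under any relabeling of the node ids and
    differs between non-isomorphic graphs.
    """
    if g.number_of_nodes() == 0:
        return CanonicalForm((), "((), ())")
    nlabel = {v: node_label(g.nodes[v]) for v in g.nodes}
    elabel = {frozenset((u, v)): edge_label(g.edges[u, v]) for u, v in g.edges}
    init_keys = {v: (repr(nlabel[v]), g.degree[v]) for v in g.nodes}
    ranked = {k: i for i, k in enumerate(sorted(set(init_keys.values())))}
    cert, order = _canon_search(g, {v: ranked[init_keys[v]] for v in g.nodes},
                                nlabel, elabel)
    return CanonicalForm(order, cert)


def certificate(g: nx.Graph, node_label: NodeLabel = _default_node_label,
                edge_label: EdgeLabel = _default_edge_label) -> str:
    return canonical_form(g, node_label, edge_label).certificate


def short_certificate(g: nx.Graph, node_label: NodeLabel = _default_node_label,
                      edge_label: EdgeLabel = _default_edge_label) -> str:
    """16-hex-char digest of the exact certificate (content addressing)."""
    return hashlib.sha256(certificate(g, node_label, edge_label).encode()).hexdigest()[:16]


# convenience wrappers for the domain graphs -------------------------------

def molecule_certificate(g: nx.Graph) -> str:
    """Species identity: certificate of the hydrogen-collapsed molecule."""
    return certificate(G.collapse_hydrogens(g), G.mol_node_label, G.order_label)


def its_certificate(g: nx.Graph, core: bool = False) -> str:
    nl = G.its_core_node_label if core else G.its_node_label
    return certificate(g, nl, G.pair_label)


# ---------------------------------------------------------------------------
# Weisfeiler--Lehman hashing
# ---------------------------------------------------------------------------

def _h(s: str) -> str:
    return hashlib.sha256(s.encode()).hexdigest()[:16]


def wl_hash(g: nx.Graph, k: int = 3, node_label: NodeLabel = _default_node_label,
            edge_label: EdgeLabel = _default_edge_label) -> WLHash:
    """Weisfeiler--Lehman graph hash with ``k`` aggregation rounds.

    ``k = 0`` digests the raw node-label multiset.  Edge labels participate
    in the aggregation so that bond orders / ITS order pairs are seen.
    """
    if k < 0:
        raise ValueError("iterations must be non-negative")
    labels = {v: _h(repr(node_label(g.nodes[v]))) for v in g.nodes}
    for _ in range(k):
        labels = {
            v: _h(repr((labels[v],
                        tuple(sorted((repr(edge_label(g.edges[v, u])), labels[u])
                                     for u in g[v])))))
            for v in g.nodes
        }
    digest = _h(repr(tuple(sorted(labels.values()))))
    return WLHash(k, digest)


# ---------------------------------------------------------------------------
# atom-map canonicalization of reactions
# ---------------------------------------------------------------------------

def canonicalize_aam(record):
    """Renumber atom maps into canonical form.

    Reactant atoms are renumbered 1..N following the exact canonical order
    of the reactant ensemble; product maps are rewritten through the
    atom-atom map.  Any two correctly-mapped variants of the same reaction
    yield the identical record (and reaction SMILES).
    """
    from .chemio import ReactionRecord  # local import to avoid a cycle

    if not record.is_balanced():
        raise ITSError("cannot canonicalize an unbalanced reaction record")
    form = canonical_form(record.reactants, G.mol_node_label, G.order_label)
    new_map = {record.reactants.nodes[v]["atom_map"]: i + 1
               for i, v in enumerate(form.ordering)}
    reactants = record.reactants.copy()
    products = record.products.copy()
    for side in (reactants, products):
        for _, d in side.nodes(data=True):
            d["atom_map"] = new_map[d["atom_map"]]
    return ReactionRecord(reactants, products)


def aam_equivalent(a, b) -> bool:
    """True iff two balanced records describe the same mapped transformation,
    i.e. their ITS graphs are isomorphic (node labels and order pairs)."""
    from .its import build_its
    from .match import is_isomorphic

    ga, gb = build_its(a), build_its(b)
    return is_isomorphic(ga, gb, node_label=G.its_node_label, edge_label=G.pair_label)


# ---------------------------------------------------------------------------
# brute-force oracle (tests / validation only)
# ---------------------------------------------------------------------------

def brute_force_isomorphic(a: nx.Graph, b: nx.Graph,
                           node_label: NodeLabel = _default_node_label,
                           edge_label: EdgeLabel = _default_edge_label) -> bool:
    """Reference isomorphism check enumerating label-compatible bijections
    (the Cartesian product of within-label-class permutations).

    Exponential; intended as an independent oracle on graphs of ~10 nodes.
    """
    from itertools import product

    if a.number_of_nodes() != b.number_of_nodes() or a.number_of_edges() != b.number_of_edges():
        return False
    classes_a: dict[str, list] = {}
    classes_b: dict[str, list] = {}
    for v in sorted(a.nodes, key=repr):
        classes_a.setdefault(repr(node_label(a.nodes[v])), []).append(v)
    for v in sorted(b.nodes, key=repr):
        classes_b.setdefault(repr(node_label(b.nodes[v])), []).append(v)
    if sorted(classes_a) != sorted(classes_b) or \
            any(len(classes_a[k]) != len(classes_b[k]) for k in classes_a):
        return False
    keys = sorted(classes_a)
    for combo in product(*(permutations(classes_b[k]) for k in keys)):
        m = {}
        for k, perm in zip(keys, combo):
            m.update(zip(classes_a[k], perm))
        ok = True
        for u, v, d in a.edges(data=True):
            if not b.has_edge(m[u], m[v]) or \
                    repr(edge_label(b.edges[m[u], m[v]])) != repr(edge_label(d)):
                ok = False
                break
        if ok:  # equal edge counts + injectivity make this a full isomorphism
            return True
    return False
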