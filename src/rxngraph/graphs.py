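"""Shared graph conventions for molecules and reaction supergraphs.

Molecules are simple undirected :class:`networkx.Graph` objects.  Node
attributes::

    element   -- element symbol ("C", "N", ...; "H" for explicit hydrogens)
    charge    -- formal charge (int)
    hcount    -- implicit/bracket hydrogen count (explicit H neighbours are
                 *not* counted here)
    radical   -- number of unpaired electrons
    atom_map  -- positive atom-map index or None
    isotope   -- mass number or 0 (inert bookkeeping)
    component -- connected-component index within an ensemble (optional)

Edges carry a single attribute ``order`` drawn from {1, 1.5, 2, 3}; aromatic
bonds are always represented as order 1.5 (inputs are aromatized on parse so
that kekule forms never leak into isomorphism checks).

ITS supergraphs reuse the same node schema but store *(before, after)* pairs
for the mutable atom states (``charge``, ``hcount``, ``radical``) and a pair
``order = (oG, oH)`` on every edge, where 0 encodes "bond absent on that
side".
"""

from __future__ import annotations

from typing import Callable, Hashable, Iterable

import networkx as nx

BOND_ORDERS = (1.0, 1.5, 2.0, 3.0)

#: default valences used for hydrogen bookkeeping of decorated atoms
DEFAULT_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2, "F": 1, "Cl": 1, "Br": 1, "I": 1, "H": 1}


def add_atom(g: nx.Graph, node: Hashable, element: str, charge: int = 0,
             hcount: int = 0, radical: int = 0, atom_map: int | None = None,
             isotope: int = 0) -> Hashable:
    g.add_node(node, element=element, charge=charge, hcount=hcount,
               radical=radical, atom_map=atom_map, isotope=isotope)
    return node


def add_bond(g: nx.Graph, u: Hashable, v: Hashable, order: float = 1.0) -> None:
    if u == v:
        raise ValueError("self-loops are not allowed in molecular graphs")
    g.add_edge(u, v, order=float(order))


# ---------------------------------------------------------------------------
# label extractors (node/edge attribute dict -> hashable label)
# ---------------------------------------------------------------------------

def mol_node_label(d: dict) -> tuple:
    """Full molecular node label: identity of a chemical species."""
    return (d["element"], d.get("charge", 0), d.get("hcount", 0), d.get("radical", 0))


def core_node_label(d: dict) -> tuple:
    """Coarse node label (element, charge) used by rules and clustering."""
    return (d["element"], d.get("charge", 0))


def order_label(d: dict) -> float:
    return d["order"]


def its_node_label(d: dict) -> tuple:
    """Full ITS node label including before/after state pairs."""
    return (d["element"], tuple(d.get("charge", (0, 0))),
            tuple(d.get("hcount", (0, 0))), tuple(d.get("radical", (0, 0))))


def its_core_node_label(d: dict) -> tuple:
    return (d["element"], tuple(d.get("charge", (0, 0))))


def pair_label(d: dict) -> tuple:
    return tuple(d["order"])


# ---------------------------------------------------------------------------
# ensembles
# ---------------------------------------------------------------------------

def assign_components(g: nx.Graph) -> int:
    """Label connected components deterministically; returns their number."""
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    for i, comp in enumerate(comps):
        for n in comp:
            g.nodes[n]["component"] = i
    return len(comps)


def component_subgraphs(g: nx.Graph) -> list[nx.Graph]:
    comps = sorted((sorted(c) for c in nx.connected_components(g)), key=lambda c: c[0])
    return [g.subgraph(c).copy() for c in comps]


def disjoint_union(graphs: Iterable[nx.Graph]) -> nx.Graph:
    """Union with integer relabeling 0..N-1; records ``component`` per node."""
    out = nx.Graph()
    offset = 0
    for i, g in enumerate(graphs):
        mapping = {n: offset + j for j, n in enumerate(sorted(g.nodes))}
        for n, d in g.nodes(data=True):
            out.add_node(mapping[n], **dict(d))
            out.nodes[mapping[n]]["component"] = i
        for u, v, d in g.edges(data=True):
            out.add_edge(mapping[u], mapping[v], **dict(d))
        offset += g.number_of_nodes()
    return out


# ---------------------------------------------------------------------------
# hydrogen bookkeeping
# ---------------------------------------------------------------------------

def _is_plain_hydrogen(g: nx.Graph, n: Hashable) -> bool:
    d = g.nodes[n]
    return (d["element"] == "H" and d.get("charge", 0) == 0
            and d.get("radical", 0) == 0 and d.get("isotope", 0) == 0
            and d.get("hcount", 0) == 0)


def collapse_hydrogens(g: nx.Graph) -> nx.Graph:
    """Fold explicit, chemically plain H atoms into their neighbour's hcount.

    H atoms that are part of an H2 molecule, isolated, charged, isotopic or
    radical are kept explicit.  Atom maps on folded hydrogens are dropped:
    the collapsed form is the species-identity normal form.
    """
    out = g.copy()
    for n in sorted(g.nodes):
        if not _is_plain_hydrogen(g, n):
            continue
        nbrs = list(g[n])
        if len(nbrs) != 1:
            continue
        m = nbrs[0]
        if g.nodes[m]["element"] == "H":
            continue  # H2: keep both explicit
        if g.edges[n, m]["order"] != 1.0:
            continue
        if n not in out:
            continue
        out.nodes[m]["hcount"] = out.nodes[m].get("hcount", 0) + 1
        out.remove_node(n)
    return out


def expand_hydrogens(g: nx.Graph) -> nx.Graph:
    """Promote every implicit hydrogen to an explicit, unmapped H node."""
    out = g.copy()
    fresh = (max((n for n in g.nodes if isinstance(n, int)), default=-1)) + 1
    for n in sorted(g.nodes):
        h = out.nodes[n].get("hcount", 0)
        if not h:
            continue
        out.nodes[n]["hcount"] = 0
        comp = out.nodes[n].get("component")
        for _ in range(h):
            add_atom(out, fresh, "H")
            if comp is not None:
                out.nodes[fresh]["component"] = comp
            add_bond(out, n, fresh, 1.0)
            fresh += 1
    return out


def element_counts(g: nx.Graph, with_implicit_h: bool = True) -> dict[str, int]:
    counts: dict[str, int] = {}
    for _, d in g.nodes(data=True):
        counts[d["element"]] = counts.get(d["element"], 0) + 1
        if with_implicit_h:
            counts["H"] = counts.get("H", 0) + d.get("hcount", 0)
    return {k: v for k, v in counts.items() if v}


def labeled_copy(g: nx.Graph, node_label: Callable[[dict], Hashable],
                 edge_label: Callable[[dict], Hashable]) -> nx.Graph:
    """Reduce a domain graph to a bare labeled graph (attrs ``label`` only)."""
    out = nx.Graph()
    for n, d in g.nodes(data=True):
        out.add_node(n, label=node_label(d))
    for u, v, d in g.edges(data=True):
        out.add_edge(u, v, label=edge_label(d))
    return out
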