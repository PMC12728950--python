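"""Imaginary Transition State (ITS) supergraphs.

An ITS superposes the reactant and the product ensemble of a balanced,
atom-mapped reaction into one graph: nodes are the mapped atoms (keyed by
their atom-map index), and each edge carries an order pair ``(oG, oH)``
where ``oG`` is the bond order among the reactants and ``oH`` among the
products, with 0 meaning "absent on that side".  An edge is *changed* iff
``oG != oH`` -- formed when ``oG == 0``, broken when ``oH == 0``.  Node
states that may change across the reaction (charge, hcount, radical) are
stored as (before, after) pairs.

Hydrogen completion: when a mapped heavy atom's hydrogen count differs
between the two sides, fresh explicit H nodes with fresh map indices are
created and paired greedily (lowest donor/acceptor map index first), so
the hydrogens participating in the transformation become explicit nodes of
the reaction center while spectator hydrogens stay implicit.
"""

from __future__ import annotations

import re

import networkx as nx

from . import graphs as G
from .chemio import ReactionRecord, parse_reaction_smiles
from .errors import ITSError


def hydrogen_completion(record: ReactionRecord) -> ReactionRecord:
    """Return a balanced copy of ``record`` with migrating hydrogens explicit.

    Handles two situations: (a) a mapped heavy atom's implicit hcount differs
    between the sides (the hydrogen moved -- fresh explicit H nodes with fresh
    maps are created on both sides), and (b) an explicit H node is mapped on
    one side only (e.g. ``[H:3][H:4]`` consumed into implicit hydrogens -- its
    counterpart is materialized on the other side, keeping its map).  Donors
    and acceptors are paired greedily, lowest map index first, so completion
    is deterministic.
    """
    for side, name in ((record.reactants, "reactant"), (record.products, "product")):
        for n, d in side.nodes(data=True):
            if not d.get("atom_map"):
                raise ITSError(f"unmapped {name} atom {n} ({d['element']}); "
                               "completion requires a fully mapped record")
    rmaps = {d["atom_map"]: n for n, d in record.reactants.nodes(data=True)}
    pmaps = {d["atom_map"]: n for n, d in record.products.nodes(data=True)}
    r_orphans = sorted(rmaps.keys() - pmaps.keys())
    p_orphans = sorted(pmaps.keys() - rmaps.keys())
    for m in r_orphans:
        if record.reactants.nodes[rmaps[m]]["element"] != "H":
            raise ITSError(f"heavy reactant atom map {m} has no product partner")
    for m in p_orphans:
        if record.products.nodes[pmaps[m]]["element"] != "H":
            raise ITSError(f"heavy product atom map {m} has no reactant partner")
    donors, acceptors = [], []  # maps of atoms losing / gaining implicit H
    for m in sorted(rmaps.keys() & pmaps.keys()):
        d = record.reactants.nodes[rmaps[m]].get("hcount", 0) - \
            record.products.nodes[pmaps[m]].get("hcount", 0)
        donors.extend([m] * max(d, 0))
        acceptors.extend([m] * max(-d, 0))
    if not (donors or acceptors or r_orphans or p_orphans):
        return record
    if len(donors) + len(r_orphans) != len(acceptors) + len(p_orphans):
        raise ITSError("hydrogen imbalance across the atom map: "
                       f"{len(donors)} + {len(r_orphans)} lost vs "
                       f"{len(acceptors)} + {len(p_orphans)} gained")
    reactants = record.reactants.copy()
    products = record.products.copy()
    fresh_map = max(rmaps | pmaps) + 1
    fresh_r = max(reactants.nodes) + 1
    fresh_p = max(products.nodes) + 1

    def attach(side, node_id, heavy, hmap):
        G.add_atom(side, node_id, "H", atom_map=hmap)
        G.add_bond(side, heavy, node_id, 1.0)
        side.nodes[heavy]["hcount"] -= 1

    # orphan explicit hydrogens keep their map; their partner is created on
    # the other side, debited from the acceptor/donor hcount
    for m in r_orphans:
        attach(products, fresh_p, pmaps[acceptors.pop(0)], m)
        fresh_p += 1
    for m in p_orphans:
        attach(reactants, fresh_r, rmaps[donors.pop(0)], m)
        fresh_r += 1
    # remaining migrations become fresh explicit pairs
    for donor, acceptor in zip(donors, acceptors):
        attach(reactants, fresh_r, rmaps[donor], fresh_map)
        attach(products, fresh_p, pmaps[acceptor], fresh_map)
        fresh_map += 1
        fresh_r += 1
        fresh_p += 1
    G.assign_components(reactants)
    G.assign_components(products)
    return ReactionRecord(reactants, products)


def build_its(record: ReactionRecord, complete_hydrogens: bool = True) -> nx.Graph:
    """Merge a balanced reaction record into its ITS supergraph."""
    if complete_hydrogens:
        record = hydrogen_completion(record)
    if not record.is_balanced():
        raise ITSError("refusing to build an ITS from an unbalanced record; "
                       "unmapped: " + "; ".join(record.unmapped()))
    aam = record.aam()
    its = nx.Graph()
    for m, (rn, pn) in aam.items():
        rd = record.reactants.nodes[rn]
        pd = record.products.nodes[pn]
        its.add_node(m, element=rd["element"],
                     charge=(rd.get("charge", 0), pd.get("charge", 0)),
                     hcount=(rd.get("hcount", 0), pd.get("hcount", 0)),
                     radical=(rd.get("radical", 0), pd.get("radical", 0)),
                     isotope=rd.get("isotope", 0))
    rmap = {rn: m for m, (rn, _) in aam.items()}
    pmap = {pn: m for m, (_, pn) in aam.items()}
    for u, v, d in record.reactants.edges(data=True):
        its.add_edge(rmap[u], rmap[v], order=(d["order"], 0.0))
    for u, v, d in record.products.edges(data=True):
        mu, mv = pmap[u], pmap[v]
        if its.has_edge(mu, mv):
            its.edges[mu, mv]["order"] = (its.edges[mu, mv]["order"][0], d["order"])
        else:
            its.add_edge(mu, mv, order=(0.0, d["order"]))
    return its


def changed_edges(its: nx.Graph) -> dict[tuple, tuple]:
    """Edges whose order pair differs, keyed by the sorted node pair."""
    return {tuple(sorted((u, v))): tuple(d["order"])
            for u, v, d in its.edges(data=True) if d["order"][0] != d["order"][1]}


def changed_nodes(its: nx.Graph) -> list:
    """Nodes whose charge or radical state changes (charge-only centers)."""
    out = []
    for n, d in its.nodes(data=True):
        if d["charge"][0] != d["charge"][1] or d["radical"][0] != d["radical"][1]:
            out.append(n)
    return sorted(out)


def reaction_center(its: nx.Graph, radius: int = 0) -> nx.Graph:
    """Reaction-center subgraph at the given environment radius.

    Radius 0 keeps only the changed edges plus their incident nodes (and
    nodes whose atom state changes with no bond change); radius r adds all
    nodes within r hops on the union connectivity, and every ITS edge among
    the included nodes.
    """
    if radius < 0:
        raise ValueError("radius must be non-negative")
    core = set()
    for (u, v) in changed_edges(its):
        core.update((u, v))
    core.update(changed_nodes(its))
    nodes = set(core)
    frontier = set(core)
    for _ in range(radius):
        nxt = {u for v in frontier for u in its[v]} - nodes
        if not nxt:
            break
        nodes |= nxt
        frontier = nxt
    if radius == 0:
        center = nx.Graph()
        for n in nodes:
            center.add_node(n, **dict(its.nodes[n]))
        for (u, v), pair in changed_edges(its).items():
            center.add_edge(u, v, order=pair)
    else:
        center = its.subgraph(nodes).copy()
    center.graph["radius"] = radius
    return center


def project(its: nx.Graph, side: str) -> nx.Graph:
    """Reactant- ('before') or product-side ('after') molecule ensemble."""
    i = {"before": 0, "reactants": 0, "after": 1, "products": 1}[side]
    g = nx.Graph()
    for n, d in its.nodes(data=True):
        G.add_atom(g, n, d["element"], charge=d["charge"][i], hcount=d["hcount"][i],
                   radical=d["radical"][i], atom_map=n, isotope=d.get("isotope", 0))
    for u, v, d in its.edges(data=True):
        if d["order"][i] > 0:
            G.add_bond(g, u, v, d["order"][i])
    G.assign_components(g)
    return g


def its_to_reaction(its: nx.Graph, validate: bool = True) -> ReactionRecord:
    """Decompose an ITS back into a reaction record.

    With ``validate=True`` both sides are checked to have a chemically
    writable valence state (via SMILES serialization); impossible states
    raise :class:`ITSError`.
    """
    record = ReactionRecord(project(its, "before"), project(its, "after"))
    if validate:
        from .chemio import write_reaction_smiles
        from .errors import SerializationError
        try:
            write_reaction_smiles(record)
        except SerializationError as exc:
            raise ITSError(f"ITS projections are not chemically valid: {exc}") from exc
    return record


def its_from_smiles(text: str, complete_hydrogens: bool = True) -> nx.Graph:
    return build_its(parse_reaction_smiles(text), complete_hydrogens)


# ---------------------------------------------------------------------------
# GML / JSON export
# ---------------------------------------------------------------------------

def its_to_gml(its: nx.Graph) -> str:
    """ITS as a flat GML graph.

    Edge labels are "(oG,oH)" order-pair strings; nodes carry the element as
    ``label`` plus the (before, after) state pairs, so the serialization is
    lossless and :func:`its_from_gml` reconstructs an isomorphic ITS.
    """
    lines = ["graph ["]
    for n, d in sorted(its.nodes(data=True)):
        state = " ".join(f'{k} "({d[k][0]:g},{d[k][1]:g})"'
                         for k in ("charge", "hcount", "radical"))
        lines.append(f'  node [ id {n} label "{d["element"]}" {state} ]')
    for u, v, d in sorted(its.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
        a, b = d["order"]
        lines.append(f'  edge [ source {min(u, v)} target {max(u, v)} '
                     f'label "({a:g},{b:g})" ]')
    lines.append("]")
    return "\n".join(lines) + "\n"


def _parse_pair(text: str) -> tuple[float, float]:
    from .errors import SchemaError
    m = re.match(r"^\(([-\d.]+),([-\d.]+)\)$", text.strip())
    if not m:
        raise SchemaError(f"malformed pair label {text!r}")
    return float(m.group(1)), float(m.group(2))


def its_from_gml(text: str) -> nx.Graph:
    """Inverse of :func:`its_to_gml`."""
    from .chemio import parse_gml
    from .errors import SchemaError

    tree = parse_gml(text)
    if len(tree) != 1 or tree[0][0] != "graph":
        raise SchemaError("expected a single top-level 'graph [...]' block")
    its = nx.Graph()
    for key, val in tree[0][1]:
        rec = dict(val)
        if key == "node":
            pairs = {k: _parse_pair(rec[k]) for k in ("charge", "hcount", "radical")}
            its.add_node(int(rec["id"]), element=rec["label"],
                         charge=tuple(int(x) for x in pairs["charge"]),
                         hcount=tuple(int(x) for x in pairs["hcount"]),
                         radical=tuple(int(x) for x in pairs["radical"]))
        elif key == "edge":
            u, v = int(rec["source"]), int(rec["target"])
            if u not in its or v not in its:
                raise SchemaError(f"edge endpoint {u},{v} not declared")
            its.add_edge(u, v, order=_parse_pair(rec["label"]))
        else:
            raise SchemaError(f"unexpected key {key!r} in ITS graph")
    return its


def its_to_json(its: nx.Graph) -> str:
    import json
    return json.dumps({
        "nodes": [{"id": n, **{k: list(v) if isinstance(v, tuple) else v
                               for k, v in d.items()}}
                  for n, d in sorted(its.nodes(data=True))],
        "edges": [{"source": min(u, v), "target": max(u, v), "order": list(d["order"])}
                  for u, v, d in sorted(its.edges(data=True),
                                        key=lambda e: (min(e[0], e[1]), max(e[0], e[1])))],
    }, indent=2)
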