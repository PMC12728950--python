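"""Parsing and writing of atom-mapped reaction SMILES and of DPO rules in
the GML rule dialect.

SMILES handling is delegated to RDKit; molecules become the labeled
:mod:`networkx` graphs described in :mod:`rxngraph.graphs`.  Aromatic
systems are perceived on parse and carried as bond order 1.5 throughout, so
kekule variants of the same ring never look different to the isomorphism
machinery.  Stereochemical tokens are parsed and dropped with a warning;
agents between the two ``>`` of a reaction SMILES are discarded with a
warning.

The GML dialect is the rule exchange format::

    rule [
      ruleID "..."
      left    [ node [...] edge [ source 1 target 2 label "-" ] ... ]
      context [ node [ id 1 label "C" ] ... ]
      right   [ ... ]
    ]

with bond labels "-", "=", "#", ":" for orders 1, 2, 3, 1.5 and node labels
of the form ``element[count][+|-]`` (e.g. ``C``, ``N+``, ``Mg2+``).  Nodes
whose charge changes across the rule are listed in *both* the left and right
sections under the same id.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx
from rdkit import Chem, RDLogger

from . import graphs as G
from .errors import ParseError, SchemaError, SerializationError, ValidationError

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.warning")

_ORDER_TO_GML = {1.0: "-", 2.0: "=", 3.0: "#", 1.5: ":"}
_GML_TO_ORDER = {v: k for k, v in _ORDER_TO_GML.items()}
_BOND_TYPES = {1.0: Chem.BondType.SINGLE, 2.0: Chem.BondType.DOUBLE,
               3.0: Chem.BondType.TRIPLE, 1.5: Chem.BondType.AROMATIC}


# ---------------------------------------------------------------------------
# reaction records
# ---------------------------------------------------------------------------

@dataclass
class ReactionRecord:
    """An atom-mapped reaction: two molecule ensembles plus the atom-atom map
    implied by matching ``atom_map`` indices."""

    reactants: nx.Graph
    products: nx.Graph

    def aam(self) -> dict[int, tuple]:
        """atom_map index -> (reactant node, product node), for maps present
        on both sides."""
        r = {d["atom_map"]: n for n, d in self.reactants.nodes(data=True)
             if d.get("atom_map")}
        p = {d["atom_map"]: n for n, d in self.products.nodes(data=True)
             if d.get("atom_map")}
        return {m: (r[m], p[m]) for m in sorted(r.keys() & p.keys())}

    def unmapped(self) -> list[str]:
        """Human-readable list of atoms without an atom-map partner."""
        out = []
        pairs = self.aam()
        for side, name in ((self.reactants, "reactant"), (self.products, "product")):
            for n, d in sorted(side.nodes(data=True)):
                m = d.get("atom_map")
                if not m or m not in pairs:
                    out.append(f"{name} atom {n} ({d['element']}, map {m})")
        return out

    def is_balanced(self) -> bool:
        """Every atom mapped on both sides with agreeing elements."""
        pairs = self.aam()
        if len(pairs) != self.reactants.number_of_nodes() or \
                len(pairs) != self.products.number_of_nodes():
            return False
        return all(self.reactants.nodes[r]["element"] == self.products.nodes[p]["element"]
                   for r, p in pairs.values())

    def to_json(self) -> str:
        def side(g):
            return {
                "nodes": [{"id": n, **{k: v for k, v in d.items()}}
                          for n, d in sorted(g.nodes(data=True))],
                "edges": [{"source": u, "target": v, "order": d["order"]}
                          for u, v, d in sorted(g.edges(data=True), key=lambda e: (e[0], e[1]))],
            }
        return json.dumps({"reactants": side(self.reactants),
                           "products": side(self.products),
                           "balanced": self.is_balanced()}, indent=2)


# ---------------------------------------------------------------------------
# SMILES -> graphs
# ---------------------------------------------------------------------------

def _mol_to_graph(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    for atom in mol.GetAtoms():
        G.add_atom(g, atom.GetIdx(), atom.GetSymbol(),
                   charge=atom.GetFormalCharge(),
                   hcount=atom.GetTotalNumHs(includeNeighbors=False),
                   radical=atom.GetNumRadicalElectrons(),
                   atom_map=atom.GetAtomMapNum() or None,
                   isotope=atom.GetIsotope())
    for bond in mol.GetBonds():
        order = bond.GetBondTypeAsDouble()
        if order not in G.BOND_ORDERS:
            raise ParseError(f"unsupported bond order {order}")
        G.add_bond(g, bond.GetBeginAtomIdx(), bond.GetEndAtomIdx(), order)
    G.assign_components(g)
    return g


def parse_smiles(text: str) -> nx.Graph:
    """Parse one molecule ensemble (``.``-separated SMILES) into a graph."""
    if re.search(r"[@/\\]", text):
        log.warning("stereochemical tokens in %r are parsed and dropped", text)
    params = Chem.SmilesParserParams()
    params.removeHs = False
    mol = Chem.MolFromSmiles(text, params)
    if mol is None:
        for token in text.split("."):
            if Chem.MolFromSmiles(token, params) is None:
                raise ParseError(f"unparsable SMILES component: {token!r}")
        raise ParseError(f"unparsable SMILES: {text!r}")
    g = _mol_to_graph(mol)
    seen: set[int] = set()
    for _, d in g.nodes(data=True):
        m = d.get("atom_map")
        if m:
            if m in seen:
                raise ValidationError(f"duplicate atom-map index {m} within one side")
            seen.add(m)
    return g


def parse_reaction_smiles(text: str) -> ReactionRecord:
    """Parse ``reactants>>products`` (or ``reactants>agents>products``; agents
    are discarded with a warning) into a :class:`ReactionRecord`."""
    parts = text.strip().split(">")
    if len(parts) != 3:
        raise ParseError(f"expected 'reactants>>products', got {text!r}")
    if parts[1]:
        log.warning("discarding agents %r from reaction SMILES", parts[1])
    return ReactionRecord(parse_smiles(parts[0]), parse_smiles(parts[2]))


# ---------------------------------------------------------------------------
# graphs -> SMILES
# ---------------------------------------------------------------------------

def graph_to_mol(g: nx.Graph) -> Chem.Mol:
    m = Chem.RWMol()
    idx = {}
    for n in sorted(g.nodes, key=repr):
        d = g.nodes[n]
        try:
            a = Chem.Atom(d["element"])
        except Exception as exc:  # unknown element symbol
            raise SerializationError(f"no SMILES token for element {d['element']!r}") from exc
        a.SetFormalCharge(int(d.get("charge", 0)))
        a.SetNoImplicit(True)
        a.SetNumExplicitHs(int(d.get("hcount", 0)))
        a.SetNumRadicalElectrons(int(d.get("radical", 0)))
        if d.get("isotope"):
            a.SetIsotope(int(d["isotope"]))
        if d.get("atom_map"):
            a.SetAtomMapNum(int(d["atom_map"]))
        idx[n] = m.AddAtom(a)
    for u, v, d in g.edges(data=True):
        m.AddBond(idx[u], idx[v], _BOND_TYPES[float(d["order"])])
        if d["order"] == 1.5:
            m.GetAtomWithIdx(idx[u]).SetIsAromatic(True)
            m.GetAtomWithIdx(idx[v]).SetIsAromatic(True)
            m.GetBondBetweenAtoms(idx[u], idx[v]).SetIsAromatic(True)
    mol = m.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception as exc:
        raise SerializationError(f"graph has no valid SMILES form: {exc}") from exc
    return mol


def write_smiles(g: nx.Graph) -> str:
    """Ensemble graph -> ``.``-joined SMILES, components in canonical order
    (sorted by their map-free canonical SMILES)."""
    parts = []
    for comp in G.component_subgraphs(g):
        mol = graph_to_mol(comp)
        bare = Chem.Mol(mol)
        for a in bare.GetAtoms():
            a.SetAtomMapNum(0)
        parts.append((Chem.MolToSmiles(bare), Chem.MolToSmiles(mol)))
    return ".".join(s for _, s in sorted(parts))


def write_reaction_smiles(r: ReactionRecord) -> str:
    return f"{write_smiles(r.reactants)}>>{write_smiles(r.products)}"


# ---------------------------------------------------------------------------
# GML rule dialect
# ---------------------------------------------------------------------------

_CHARGE_RE = re.compile(r"^([A-Z][a-z]?|\*)(\d*)([+-])?$")


def _parse_node_label(label: str) -> tuple[str, int]:
    m = _CHARGE_RE.match(label)
    if not m:
        raise SchemaError(f"malformed node label {label!r}")
    element, count, sign = m.groups()
    if sign is None:
        if count:
            raise SchemaError(f"malformed node label {label!r}")
        return element, 0
    mag = int(count) if count else 1
    return element, mag if sign == "+" else -mag


def _format_node_label(element: str, charge: int) -> str:
    if charge == 0:
        return element
    mag = abs(charge)
    return f"{element}{mag if mag > 1 else ''}{'+' if charge > 0 else '-'}"


def _tokenize_gml(text: str) -> list[str]:
    tokens = re.findall(r'"[^"]*"|\[|\]|[^\s\[\]]+', text)
    return tokens


def _parse_gml_list(tokens: list[str], i: int) -> tuple[list, int]:
    out = []
    while i < len(tokens):
        tok = tokens[i]
        if tok == "]":
            return out, i + 1
        key = tok
        i += 1
        if i >= len(tokens):
            raise SchemaError(f"dangling key {key!r} at end of GML")
        val = tokens[i]
        if val == "[":
            sub, i = _parse_gml_list(tokens, i + 1)
            out.append((key, sub))
        else:
            out.append((key, val.strip('"')))
            i += 1
    return out, i


def parse_gml(text: str) -> list:
    """Whitespace-insensitive parse of the GML dialect into (key, value) lists."""
    tokens = _tokenize_gml(text)
    tree, i = _parse_gml_list(tokens, 0)
    if i != len(tokens):
        raise SchemaError("unbalanced brackets in GML text")
    return tree


def _section_items(section: list) -> tuple[list[dict], list[dict]]:
    nodes, edges = [], []
    for key, val in section:
        rec = dict(val) if isinstance(val, list) else None
        if key == "node":
            if rec is None or "id" not in rec or "label" not in rec:
                raise SchemaError("node record needs id and label")
            nodes.append({"id": int(rec["id"]), "label": rec["label"]})
        elif key == "edge":
            if rec is None or not {"source", "target", "label"} <= rec.keys():
                raise SchemaError("edge record needs source, target and label")
            edges.append({"source": int(rec["source"]), "target": int(rec["target"]),
                          "label": rec["label"]})
        else:
            raise SchemaError(f"unexpected key {key!r} in rule section")
    return nodes, edges


def gml_to_rule(text: str):
    """Parse GML rule text into a :class:`rxngraph.rules.RuleSpan`."""
    from .rules import RuleSpan

    tree = parse_gml(text)
    if len(tree) != 1 or tree[0][0] != "rule" or not isinstance(tree[0][1], list):
        raise SchemaError("expected a single top-level 'rule [...]' block")
    rule_id = ""
    sections = {"left": ([], []), "context": ([], []), "right": ([], [])}
    implicit: list[frozenset] = []
    for key, val in tree[0][1]:
        if key == "ruleID":
            rule_id = str(val)
        elif key in sections:
            sections[key] = _section_items(val)
        elif key == "implicit":
            for gkey, gval in val:
                if gkey != "group":
                    raise SchemaError("implicit section may only contain group blocks")
                implicit.append(frozenset(int(v) for _, v in gval))
        else:
            raise SchemaError(f"unexpected key {key!r} in rule")

    ctx_nodes = {n["id"]: _parse_node_label(n["label"]) for n in sections["context"][0]}
    left_nodes = {n["id"]: _parse_node_label(n["label"]) for n in sections["left"][0]}
    right_nodes = {n["id"]: _parse_node_label(n["label"]) for n in sections["right"][0]}

    L, R = nx.Graph(), nx.Graph()
    for nid, (el, ch) in {**ctx_nodes, **left_nodes}.items():
        L.add_node(nid, element=el, charge=ch)
    for nid, (el, ch) in {**ctx_nodes, **right_nodes}.items():
        R.add_node(nid, element=el, charge=ch)

    def place(graphs: Iterable[nx.Graph], edges: list[dict]) -> None:
        for e in edges:
            if e["label"] not in _GML_TO_ORDER:
                raise SchemaError(f"unknown bond label {e['label']!r}")
            for g in graphs:
                for nid in (e["source"], e["target"]):
                    if nid not in g:
                        raise SchemaError(f"edge endpoint {nid} not declared")
                g.add_edge(e["source"], e["target"], order=_GML_TO_ORDER[e["label"]])

    place([L, R], sections["context"][1])
    place([L], sections["left"][1])
    place([R], sections["right"][1])

    K = nx.Graph()
    for nid in sorted(L.nodes & R.nodes):
        K.add_node(nid, element=L.nodes[nid]["element"])
    for u, v, d in L.edges(data=True):
        if R.has_edge(u, v) and R.edges[u, v]["order"] == d["order"]:
            K.add_edge(u, v, order=d["order"])
    rule = RuleSpan(L, K, R, rule_id or None, tuple(implicit))
    rule.validate()
    return rule


def rule_to_gml(rule) -> str:
    """Serialize a RuleSpan to the GML dialect (2-space indentation; sections
    ordered ruleID, left, context, right)."""
    L, K, R = rule.left, rule.context, rule.right
    left_nodes, ctx_nodes, right_nodes = [], [], []
    for nid in sorted(set(L.nodes) | set(R.nodes)):
        in_l, in_r = nid in L, nid in R
        if in_l and in_r:
            lch = L.nodes[nid].get("charge", 0)
            rch = R.nodes[nid].get("charge", 0)
            el = L.nodes[nid]["element"]
            if lch == rch:
                ctx_nodes.append((nid, _format_node_label(el, lch)))
            else:
                left_nodes.append((nid, _format_node_label(el, lch)))
                right_nodes.append((nid, _format_node_label(el, rch)))
        elif in_l:
            left_nodes.append((nid, _format_node_label(L.nodes[nid]["element"],
                                                       L.nodes[nid].get("charge", 0))))
        else:
            right_nodes.append((nid, _format_node_label(R.nodes[nid]["element"],
                                                        R.nodes[nid].get("charge", 0))))
    ctx_edges, left_edges, right_edges = [], [], []
    for u, v, d in sorted(L.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
        if K.has_edge(u, v):
            ctx_edges.append((min(u, v), max(u, v), _ORDER_TO_GML[d["order"]]))
        else:
            left_edges.append((min(u, v), max(u, v), _ORDER_TO_GML[d["order"]]))
    for u, v, d in sorted(R.edges(data=True), key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
        if not K.has_edge(u, v):
            right_edges.append((min(u, v), max(u, v), _ORDER_TO_GML[d["order"]]))

    lines = ["rule [", f'  ruleID "{rule.rule_id}"']

    def emit(name: str, nodes, edges):
        lines.append(f"  {name} [")
        for nid, lab in nodes:
            lines.append(f'    node [ id {nid} label "{lab}" ]')
        for u, v, lab in edges:
            lines.append(f'    edge [ source {u} target {v} label "{lab}" ]')
        lines.append("  ]")

    emit("left", left_nodes, left_edges)
    emit("context", ctx_nodes, ctx_edges)
    emit("right", right_nodes, right_edges)
    if rule.implicit:
        lines.append("  implicit [")
        for group in rule.implicit:
            ids = " ".join(f"id {i}" for i in sorted(group))
            lines.append(f"    group [ {ids} ]")
        lines.append("  ]")
    lines.append("]")
    return "\n".join(lines) + "\n"
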