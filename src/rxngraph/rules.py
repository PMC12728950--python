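"""DPO rule spans: extraction from reaction centers, inversion, composition.

A rule is a span ``L <- K -> R`` of labeled graphs sharing node ids: ``L``
is the full left pattern (all nodes plus bonds present before the
transformation), ``R`` the full right pattern, and ``K`` the preserved
interface (all shared nodes, plus the bonds whose order is unchanged).
Because chemical transformations conserve atoms, ``K`` normally contains
every node; node deletion/creation is still supported for generality.
Rule nodes constrain element and formal charge only -- hydrogen counts are
deliberately unconstrained so that coarse rules generalize, with hydrogens
that take part in the transformation appearing as explicit H nodes.

Composition glues a second rule's left pattern onto the first rule's right
pattern.  ``compose`` overlaps every component of ``L2`` that embeds into
``R1`` ("as available"); components that cannot embed remain explicit
co-reactants of the composite.  ``partial_compose`` additionally enumerates
leaving each embeddable component un-overlapped, either as an explicit
requirement or flagged *implicit* (condition-sourced), which yields rules
applicable without an explicit co-reagent (e.g. hydrogenation without an
explicit H2).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import networkx as nx

from . import canon
from . import graphs as G
from . import match
from .errors import RuleError


def _rule_node_label(d: dict) -> tuple:
    return (d["element"], d.get("charge", 0))


@dataclass
class RuleSpan:
    """A DPO rule span L <- K -> R with identity morphisms on shared ids."""

    left: nx.Graph
    context: nx.Graph
    right: nx.Graph
    rule_id: str | None = None
    implicit: tuple[frozenset, ...] = ()

    def __post_init__(self):
        if self.rule_id is None:
            self.rule_id = "r_" + canon.short_certificate(
                self.to_its(), _its_composite_label, G.pair_label)

    def validate(self) -> None:
        L, K, R = self.left, self.context, self.right
        if not (set(K.nodes) <= set(L.nodes) and set(K.nodes) <= set(R.nodes)):
            raise RuleError("context nodes must embed into both L and R")
        for u, v, d in K.edges(data=True):
            for g, name in ((L, "left"), (R, "right")):
                if not g.has_edge(u, v) or g.edges[u, v]["order"] != d["order"]:
                    raise RuleError(f"context edge ({u},{v}) missing from {name}")
        for n in K.nodes:
            if L.nodes[n]["element"] != R.nodes[n]["element"]:
                raise RuleError(f"element of node {n} changes across the rule")
        for group in self.implicit:
            if not group <= set(L.nodes):
                raise RuleError("implicit groups must be left-pattern nodes")

    # -- views -------------------------------------------------------------

    def to_its(self) -> nx.Graph:
        """The rule as an ITS-style graph with order pairs and state pairs."""
        its = nx.Graph()
        implicit_nodes = set().union(*self.implicit) if self.implicit else set()
        for n in set(self.left.nodes) | set(self.right.nodes):
            ld = self.left.nodes.get(n)
            rd = self.right.nodes.get(n)
            el = (ld if ld is not None else rd)["element"]
            cb = (ld if ld is not None else rd).get("charge", 0)
            ca = (rd if rd is not None else ld).get("charge", 0)
            its.add_node(n, element=el, charge=(cb, ca),
                         hcount=(0, 0), radical=(0, 0),
                         implicit=n in implicit_nodes,
                         only_in=None if (ld is not None and rd is not None)
                         else ("L" if ld is not None else "R"))
        for u, v, d in self.left.edges(data=True):
            its.add_edge(u, v, order=(d["order"], 0.0))
        for u, v, d in self.right.edges(data=True):
            if its.has_edge(u, v):
                its.edges[u, v]["order"] = (its.edges[u, v]["order"][0], d["order"])
            else:
                its.add_edge(u, v, order=(0.0, d["order"]))
        return its

    def changed_edges(self) -> dict[tuple, tuple]:
        from .its import changed_edges
        return changed_edges(self.to_its())

    def is_identity(self) -> bool:
        return not self.changed_edges() and all(
            self.left.nodes[n].get("charge", 0) == self.right.nodes[n].get("charge", 0)
            for n in self.context.nodes)

    def certificate(self) -> str:
        return canon.certificate(self.to_its(), _its_composite_label, G.pair_label)

    def copy(self) -> "RuleSpan":
        return RuleSpan(self.left.copy(), self.context.copy(), self.right.copy(),
                        self.rule_id, self.implicit)


def _its_composite_label(d: dict) -> tuple:
    return (d["element"], tuple(d.get("charge", (0, 0))), d.get("implicit", False),
            d.get("only_in"))


def rule_from_its(its: nx.Graph, rule_id: str | None = None,
                  implicit: tuple[frozenset, ...] = ()) -> RuleSpan:
    """Build a rule span from an ITS-style graph (order pairs, charge pairs)."""
    L, K, R = nx.Graph(), nx.Graph(), nx.Graph()
    for n, d in its.nodes(data=True):
        ch = d.get("charge", (0, 0))
        only = d.get("only_in")
        if only != "R":
            L.add_node(n, element=d["element"], charge=ch[0])
        if only != "L":
            R.add_node(n, element=d["element"], charge=ch[1])
        if only is None:
            K.add_node(n, element=d["element"])
    for u, v, d in its.edges(data=True):
        a, b = d["order"]
        if a > 0:
            L.add_edge(u, v, order=a)
        if b > 0:
            R.add_edge(u, v, order=b)
        if a == b and a > 0:
            K.add_edge(u, v, order=a)
    return RuleSpan(L, K, R, rule_id, implicit)


def extract_rule(center: nx.Graph, rule_id: str | None = None) -> RuleSpan:
    """Turn a reaction-center ITS (any radius) into a DPO rule span."""
    if center.number_of_nodes() == 0:
        raise RuleError("cannot extract a rule from an empty reaction center")
    return rule_from_its(center, rule_id)


def invert_rule(rule: RuleSpan) -> RuleSpan:
    """Swap left and right; an involution."""
    return RuleSpan(rule.right.copy(), rule.context.copy(), rule.left.copy(),
                    None if rule.rule_id.startswith("r_") else rule.rule_id + "_inv",
                    rule.implicit)


def identity_rule(pattern: nx.Graph, rule_id: str | None = None) -> RuleSpan:
    """K = L = R rule from a molecule-style pattern graph."""
    g = pattern.copy()
    for _, d in g.nodes(data=True):
        d.setdefault("charge", 0)
    K = g.copy()
    return RuleSpan(g.copy(), K, g.copy(), rule_id)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def _overlap_embeddings(comp: nx.Graph, r1: nx.Graph, p2: RuleSpan) -> list[dict]:
    """Embeddings of one L2 component into R1, requiring state continuity:
    the bond order / charge p1 leaves behind must equal what p2 expects."""
    return match.find_embeddings(
        comp, r1, induced=False,
        node_label=_rule_node_label, edge_label=lambda d: d["order"])


def _glue(g1: nx.Graph, p2: RuleSpan, assignment: dict, implicit_comps: list[set]) -> nx.Graph | None:
    """Glue p2's ITS onto p1's ITS (g1) along ``assignment`` (L2 node -> g1
    node; unmatched L2 nodes become fresh).  Returns the composite ITS."""
    g2 = p2.to_its()
    out = g1.copy()
    fresh = max((n for n in g1.nodes), default=0) + 1
    mapping = dict(assignment)
    implicit_nodes = set().union(*implicit_comps) if implicit_comps else set()
    for n, d in g2.nodes(data=True):
        if n in mapping:
            tgt = mapping[n]
            # charge continuity was enforced during matching; apply p2's end state
            cb = out.nodes[tgt]["charge"][0]
            out.nodes[tgt]["charge"] = (cb, d["charge"][1])
        else:
            mapping[n] = fresh
            out.add_node(fresh, element=d["element"], charge=d["charge"],
                         hcount=(0, 0), radical=(0, 0),
                         implicit=n in implicit_nodes, only_in=d.get("only_in"))
            fresh += 1
    for u, v, d in g2.edges(data=True):
        mu, mv = mapping[u], mapping[v]
        a2, b2 = d["order"]
        if out.has_edge(mu, mv):
            a1, b1 = out.edges[mu, mv]["order"]
            if u in assignment and v in assignment and a2 > 0 and b1 != a2:
                return None  # inconsistent gluing
            out.edges[mu, mv]["order"] = (a1, b2)
        else:
            if u in assignment and v in assignment and a2 > 0:
                return None  # L2 expects a bond p1 does not leave behind
            out.add_edge(mu, mv, order=(a2, b2))
    # drop bonds that vanish on both sides of the composite
    for u, v in [(u, v) for u, v, d in out.edges(data=True) if d["order"] == (0.0, 0.0)]:
        out.remove_edge(u, v)
    return out


def _enumerate_composites(p1: RuleSpan, p2: RuleSpan, partial: bool) -> list[RuleSpan]:
    g1 = p1.to_its()
    r1 = nx.Graph()
    for n, d in g1.nodes(data=True):
        if d.get("only_in") != "L":
            r1.add_node(n, element=d["element"], charge=d["charge"][1])
    for u, v, d in g1.edges(data=True):
        if d["order"][1] > 0 and r1.has_node(u) and r1.has_node(v):
            r1.add_edge(u, v, order=d["order"][1])

    comps = [p2.left.subgraph(c).copy()
             for c in sorted((sorted(c, key=repr) for c in
                              nx.connected_components(p2.left)), key=repr)]
    options_per_comp = []
    for comp in comps:
        embs = _overlap_embeddings(comp, r1, p2)
        opts: list = []
        if partial:
            opts.append(("explicit", None))
            opts.append(("implicit", None))
            opts.extend(("embed", e) for e in embs)
        else:
            # full composition: overlap wherever an overlap exists
            if embs:
                opts.extend(("embed", e) for e in embs)
            else:
                opts.append(("explicit", None))
        options_per_comp.append(opts)

    seen: set[str] = set()
    out: list[RuleSpan] = []
    for choice in itertools.product(*options_per_comp):
        assignment: dict = {}
        implicit_comps: list[set] = []
        ok = True
        used: set = set()
        for comp, (kind, emb) in zip(comps, choice):
            if kind == "embed":
                if used & set(emb.values()):
                    ok = False
                    break
                used |= set(emb.values())
                assignment.update(emb)
            elif kind == "implicit":
                implicit_comps.append(set(comp.nodes))
        if not ok:
            continue
        glued = _glue(g1, p2, assignment, implicit_comps)
        if glued is None:
            continue
        implicit_groups = _implicit_components(glued)
        composite = rule_from_its(glued, implicit=implicit_groups)
        cert = composite.certificate()
        if cert in seen:
            continue
        seen.add(cert)
        out.append(composite)
    out.sort(key=lambda r: r.certificate())
    return out


def _implicit_components(its: nx.Graph) -> tuple[frozenset, ...]:
    """Group flagged implicit nodes into left-pattern connected components."""
    flagged = {n for n, d in its.nodes(data=True) if d.get("implicit")}
    if not flagged:
        return ()
    left = nx.Graph()
    for n, d in its.nodes(data=True):
        if d.get("only_in") != "R":
            left.add_node(n)
    for u, v, d in its.edges(data=True):
        if d["order"][0] > 0 and u in left and v in left:
            left.add_edge(u, v)
    groups = []
    for comp in nx.connected_components(left):
        sel = comp & flagged
        if sel:
            groups.append(frozenset(sel))
    return tuple(sorted(groups, key=sorted))


def compose(p1: RuleSpan, p2: RuleSpan) -> list[RuleSpan]:
    """Full composition: one composite per distinct maximal overlap of p2's
    left pattern with p1's right pattern; unmatched components stay explicit."""
    return _enumerate_composites(p1, p2, partial=False)


def partial_compose(p1: RuleSpan, p2: RuleSpan) -> list[RuleSpan]:
    """Partial composition over all (possibly empty) component overlaps;
    un-overlapped L2 components may be flagged implicit (condition-sourced)."""
    return _enumerate_composites(p1, p2, partial=True)


def element_multisets(rule: RuleSpan) -> tuple[dict, dict]:
    """Element counts on each side (implicit-flagged atoms included):
    composites must conserve mass."""
    return (G.element_counts(rule.left, with_implicit_h=False),
            G.element_counts(rule.right, with_implicit_h=False))
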