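"""DPO rewriting of molecule ensembles.

``apply`` locates embeddings of a rule's left pattern in a substrate
ensemble, filters them (component-covering by default), checks the DPO
gluing condition, and performs the double pushout: delete the bonds and
atoms of L \\ K, keep K, add R \\ K, and update atom states.  The derived
reaction carries a full substrate-to-product atom mapping.

Implicit hydrogens are handled by subsumption: whenever the left pattern
contains explicit H nodes, the substrate's implicit hydrogens are promoted
to explicit nodes for matching, and product ensembles are reported both
explicitly and in hydrogen-collapsed canonical form.  Two safeguards curb
combinatorial explosion: ``embed_threshold`` hard-caps the number of
enumerated embeddings, and ``embed_pre_filter`` discards rule/substrate
pairs whose *estimated* embedding count (a product of per-node candidate
counts, an admissible over-estimate) already exceeds the cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from . import canon
from . import graphs as G
from .chemio import ReactionRecord
from .errors import ValidationError
from .match import find_embeddings
from .rules import RuleSpan, _rule_node_label, invert_rule


@dataclass
class RewriteResult:
    """One admissible rewrite: product ensemble, the embedding used, and the
    fully atom-mapped derived reaction."""
    products: nx.Graph
    embedding: dict
    derived_reaction: ReactionRecord
    truncated: bool = False

    @property
    def product_certificates(self) -> tuple[str, ...]:
        return tuple(sorted(canon.molecule_certificate(c)
                            for c in G.component_subgraphs(self.products)))

    def product_smiles(self) -> str:
        from .chemio import write_smiles
        return write_smiles(G.collapse_hydrogens(self.products))


class ApplyOutcome(list):
    """List of RewriteResults; ``truncated`` is True when a safeguard fired."""
    truncated: bool = False


def _matchable_left(rule: RuleSpan) -> nx.Graph:
    """Left pattern minus condition-sourced (implicit) components."""
    skip = set().union(*rule.implicit) if rule.implicit else set()
    return rule.left.subgraph([n for n in rule.left.nodes if n not in skip]).copy()


def estimate_embeddings(rule: RuleSpan, substrate: nx.Graph) -> int:
    """Admissible over-estimate of the embedding count.

    Per left-pattern component, the bound is the number of label-compatible
    anchors for a root node times, along a spanning tree, the worst-case
    branching of the substrate for each (parent label, bond order, child
    label) step; the
    total is the product over components.  Always >= the true count, and 0
    exactly when some pattern label is absent.
    """
    Lm = _matchable_left(rule)
    sub = substrate
    if any(Lm.nodes[n]["element"] == "H" for n in Lm.nodes):
        sub = G.expand_hydrogens(substrate)
    counts: dict[tuple, int] = {}
    branch: dict[tuple, int] = {}
    for u, d in sub.nodes(data=True):
        counts[_rule_node_label(d)] = counts.get(_rule_node_label(d), 0) + 1
        local: dict[tuple, int] = {}
        for v in sub[u]:
            key = (_rule_node_label(d), sub.edges[u, v]["order"],
                   _rule_node_label(sub.nodes[v]))
            local[key] = local.get(key, 0) + 1
        for key, c in local.items():
            branch[key] = max(branch.get(key, 0), c)
    est = 1
    for comp in nx.connected_components(Lm):
        comp = sorted(comp, key=repr)
        root = min(comp, key=lambda n: counts.get(_rule_node_label(Lm.nodes[n]), 0))
        est_c = counts.get(_rule_node_label(Lm.nodes[root]), 0)
        seen = {root}
        frontier = [root]
        while frontier and est_c:
            nxt = []
            for u in frontier:
                for v in sorted(Lm[u], key=repr):
                    if v in seen:
                        continue
                    seen.add(v)
                    nxt.append(v)
                    key = (_rule_node_label(Lm.nodes[u]),
                           Lm.edges[u, v]["order"], _rule_node_label(Lm.nodes[v]))
                    est_c *= branch.get(key, 0)
            frontier = nxt
        est *= est_c
        if est == 0:
            return 0
    return est


def _component_covering(Lm: nx.Graph, substrate: nx.Graph, emb: dict) -> bool:
    """Each pattern component must hit its own substrate molecule and every
    substrate molecule must be hit: the induced map from pattern components
    to substrate components is a bijection."""
    sub_comp = {n: substrate.nodes[n].get("component", 0) for n in substrate.nodes}
    images = set()
    for comp in nx.connected_components(Lm):
        host_comps = {sub_comp[emb[n]] for n in comp}
        # a connected pattern lands in one component by construction
        c = host_comps.pop()
        if c in images:
            return False  # two pattern molecules inside one substrate molecule
        images.add(c)
    return images == set(sub_comp.values())


def _gluing_ok(rule: RuleSpan, Lm: nx.Graph, host: nx.Graph, emb: dict) -> bool:
    """Dangling condition: a node deleted by the rule must have no host bonds
    beyond the images of its left-pattern bonds."""
    deleted = [n for n in Lm.nodes if n not in rule.right]
    for n in deleted:
        hn = emb[n]
        matched = {emb[u] for u in Lm[n]}
        if set(host[hn]) - matched:
            return False
    return True


def apply(rule: RuleSpan, substrate: nx.Graph,
          mode: str = "component_covering", direction: str = "forward",
          embed_threshold: int = 5000, embed_pre_filter: bool = True) -> ApplyOutcome:
    """Apply a DPO rule to a substrate ensemble.

    Parameters follow the engine contract: ``mode`` is ``component_covering``
    or ``unconstrained``; ``direction=backward`` applies the inverted rule.
    Results are deduplicated by canonical product certificates and returned
    in deterministic (certificate-sorted) order.
    """
    if mode not in ("component_covering", "unconstrained"):
        raise ValidationError(f"unknown matching mode {mode!r}")
    if direction not in ("forward", "backward"):
        raise ValidationError(f"unknown direction {direction!r}")
    rule.validate()
    if direction == "backward":
        rule = invert_rule(rule)

    out = ApplyOutcome()
    if substrate.number_of_nodes() == 0:
        return out

    Lm = _matchable_left(rule)
    host = substrate.copy()
    if any(Lm.nodes[n]["element"] == "H" for n in Lm.nodes):
        host = G.expand_hydrogens(host)

    if embed_pre_filter and estimate_embeddings(rule, substrate) > embed_threshold:
        out.truncated = True
        return out

    embeddings = find_embeddings(Lm, host, node_label=_rule_node_label,
                                 edge_label=lambda d: d["order"],
                                 limit=embed_threshold + 1)
    if len(embeddings) > embed_threshold:
        embeddings = embeddings[:embed_threshold]
        out.truncated = True

    seen: set[tuple] = set()
    results: list[RewriteResult] = []
    for emb in embeddings:
        if mode == "component_covering" and not _component_covering(Lm, host, emb):
            continue
        if not _gluing_ok(rule, Lm, host, emb):
            continue
        res = _rewrite(rule, host, emb)
        if res is None:
            continue
        key = res.product_certificates
        if key in seen:
            continue
        seen.add(key)
        results.append(res)
    results.sort(key=lambda r: r.product_certificates)
    out.extend(results)
    out.truncated = out.truncated or any(r.truncated for r in results)
    return out


def _rewrite(rule: RuleSpan, host: nx.Graph, emb: dict) -> RewriteResult | None:
    emb = dict(emb)
    work = host.copy()
    fresh = max(work.nodes, default=-1) + 1

    # materialize condition-sourced components as fresh substrate atoms
    for group in rule.implicit:
        for n in sorted(group):
            d = rule.left.nodes[n]
            G.add_atom(work, fresh, d["element"], charge=d.get("charge", 0))
            emb[n] = fresh
            fresh += 1
        for u in sorted(group):
            for v in rule.left[u]:
                if v in group and emb[v] > emb[u]:
                    G.add_bond(work, emb[u], emb[v], rule.left.edges[u, v]["order"])

    reactants = work.copy()

    # delete / reorder left-pattern bonds
    for u, v, d in rule.left.edges(data=True):
        hu, hv = emb[u], emb[v]
        if rule.right.has_edge(u, v):
            work.edges[hu, hv]["order"] = rule.right.edges[u, v]["order"]
        else:
            work.remove_edge(hu, hv)
    # delete L-only nodes (gluing condition already checked)
    for n in rule.left.nodes:
        if n not in rule.right:
            work.remove_node(emb[n])
    # create R-only nodes
    for n in sorted(set(rule.right.nodes) - set(rule.left.nodes), key=repr):
        d = rule.right.nodes[n]
        G.add_atom(work, fresh, d["element"], charge=d.get("charge", 0))
        emb[n] = fresh
        fresh += 1
    # add newly formed bonds and apply state changes
    for u, v, d in rule.right.edges(data=True):
        hu, hv = emb[u], emb[v]
        if not work.has_edge(hu, hv):
            work.add_edge(hu, hv, order=d["order"])
    for n in rule.right.nodes:
        if n in rule.left:
            work.nodes[emb[n]]["charge"] = rule.right.nodes[n].get("charge", 0)

    G.assign_components(work)
    G.assign_components(reactants)

    # full atom mapping: substrate atoms keep their index+1 as map
    rmapped = reactants.copy()
    pmapped = work.copy()
    mapping = {n: i + 1 for i, n in enumerate(sorted(reactants.nodes))}
    nxt = len(mapping) + 1
    for n in sorted(pmapped.nodes):
        if n not in mapping:
            mapping[n] = nxt
            nxt += 1
    for g in (rmapped, pmapped):
        for n in g.nodes:
            g.nodes[n]["atom_map"] = mapping[n]
    derived = ReactionRecord(rmapped, pmapped)
    return RewriteResult(work, emb, derived)
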