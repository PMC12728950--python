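"""Mechanistic Transition Graphs: concatenation of stepwise ITS graphs.

An n-step mechanism is stored as a single graph whose bonds carry order
vectors ``o[0..n]`` (``o[0]`` the pre-mechanism state, ``o[t]`` the state
after step t) and whose atoms carry equally long state vectors for charge,
hcount and radical, plus a presence flag for species entering mid-mechanism.
Slicing at step t recovers the step's ITS as order pairs ``(o[t-1], o[t])``;
collapsing to ``(o[0], o[n])`` gives the net reaction, which elides
transient features (e.g. a tautomerization proton shuttle): a bond is
*transient* iff ``o[0] = o[n] = 0`` with some interior entry positive.

Alignment of step t onto the accumulated intermediate uses atom-map
identity when the step graphs share a globally consistent numbering, and
otherwise a label-preserving embedding of each connected component of the
step's reactant projection; components that do not embed are new species
entering at that step.  Linear chains only -- branching mechanisms are
rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from . import graphs as G
from .errors import StitchError
from .its import project
from .match import find_embeddings

_STATE_KEYS = ("charge", "hcount", "radical")


@dataclass
class MTG:
    steps: int
    graph: nx.Graph
    alignment: list[dict] = field(default_factory=list)  # per step: ITS node -> MTG node

    def transient_bonds(self) -> list[tuple]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            o = d["order"]
            if o[0] == 0 and o[-1] == 0 and any(x > 0 for x in o[1:-1]):
                out.append(tuple(sorted((u, v))))
        return sorted(out)

    def to_json(self) -> str:
        import json
        g = self.graph
        return json.dumps({
            "steps": self.steps,
            "nodes": [{"id": n, "element": d["element"],
                       **{k: list(d[k]) for k in _STATE_KEYS},
                       "present": list(d["present"])}
                      for n, d in sorted(g.nodes(data=True))],
            "bonds": [{"source": min(u, v), "target": max(u, v), "order": list(d["order"])}
                      for u, v, d in sorted(g.edges(data=True),
                                            key=lambda e: (min(e[0], e[1]), max(e[0], e[1])))],
        }, indent=2)

    def to_dot(self) -> str:
        lines = ["graph mtg {"]
        for n, d in sorted(self.graph.nodes(data=True)):
            lines.append(f'  {n} [label="{d["element"]}{n}"];')
        for u, v, d in sorted(self.graph.edges(data=True),
                              key=lambda e: (min(e[0], e[1]), max(e[0], e[1]))):
            o = ",".join(f"{x:g}" for x in d["order"])
            lines.append(f'  {min(u, v)} -- {max(u, v)} [label="({o})"];')
        lines.append("}")
        return "\n".join(lines) + "\n"


def _its_states(its: nx.Graph, n: int) -> dict:
    d = its.nodes[n]
    return {k: tuple(d.get(k, (0, 0))) for k in _STATE_KEYS}


def _is_plain_step_h(its: nx.Graph, n) -> bool:
    d = its.nodes[n]
    return (d["element"] == "H" and tuple(d.get("charge", (0, 0))) == (0, 0)
            and tuple(d.get("radical", (0, 0))) == (0, 0))


def _mtg_h_neighbors(g: nx.Graph, m, t: int) -> list:
    """Explicit plain hydrogens bonded to MTG node m in the state after step t."""
    out = []
    for h in g[m]:
        d = g.nodes[h]
        if d["element"] == "H" and d["charge"][t] == 0 and d["radical"][t] == 0 \
                and g.edges[m, h]["order"][t] == 1.0 and d["present"][t]:
            out.append(h)
    return sorted(out)


def _map_alignment(g: nx.Graph, map_of: dict, its: nx.Graph) -> dict | None:
    """Alignment by atom-map identity; None when the step shares no maps with
    the accumulated mechanism (or the shared maps are clearly meaningless,
    i.e. elements disagree)."""
    overlap = sorted(set(its.nodes) & set(map_of), key=repr)
    if not overlap:
        return None
    for n in overlap:
        if g.nodes[map_of[n]]["element"] != its.nodes[n]["element"]:
            return None
    return {n: map_of[n] for n in overlap}


def _embedding_alignment(g: nx.Graph, its: nx.Graph, t: int) -> dict:
    """Component-wise embedding of the hydrogen-collapsed reactant projection
    of the step into the collapsed intermediate after step t-1; components
    without an embedding are new species entering at this step.  The mapping
    covers heavy atoms (and explicit H without a heavy neighbour, e.g. H2);
    remaining explicit step hydrogens are reconciled afterwards."""
    inter = nx.Graph()
    for n, d in g.nodes(data=True):
        if d["present"][t]:
            inter.add_node(n, element=d["element"],
                           **{k: d[k][t] for k in _STATE_KEYS})
    for u, v, d in g.edges(data=True):
        if d["order"][t] > 0 and u in inter and v in inter:
            inter.add_edge(u, v, order=d["order"][t])
    inter_c = G.collapse_hydrogens(inter)
    proj_c = G.collapse_hydrogens(project(its, "before"))
    shared: dict = {}
    used: set = set()
    for comp_nodes in sorted((sorted(c, key=repr) for c in
                              nx.connected_components(proj_c)), key=repr):
        comp = proj_c.subgraph(comp_nodes)
        embs = find_embeddings(comp, inter_c,
                               node_label=G.mol_node_label,
                               edge_label=lambda d: d["order"])
        embs = [e for e in embs if not used & set(e.values())]
        if not embs:
            continue  # new species entering at this step
        best = embs[0]  # deterministic: sorted by host images
        shared.update(best)
        used |= set(best.values())
    return shared


def build_mtg(steps: Sequence[nx.Graph]) -> MTG:
    """Stitch an ordered sequence of step ITS graphs into one MTG.

    Hydrogen bookkeeping is reconciled between a step and the accumulated
    intermediate: a hydrogen the step treats explicitly but the mechanism
    carries implicitly is materialized retroactively, and one the mechanism
    carries explicitly while the step counts it implicitly is treated as a
    spectator (per-node hcount slack).  Irreconcilable states -- wrong total
    hydrogen counts, disagreeing charges or bond orders on shared atoms --
    raise :class:`StitchError` with the step index.
    """
    steps = list(steps)
    if not steps:
        raise StitchError("a mechanism needs at least one step")
    g = nx.Graph()
    alignment: list[dict] = []
    map_of: dict = {}  # ITS node id -> MTG node id (for map-consistent input)
    fresh = 0

    def add_atom_vec(its, n, t):
        nonlocal fresh
        st = _its_states(its, n)
        g.add_node(fresh, element=its.nodes[n]["element"],
                   **{k: [st[k][0]] * (t + 1) + [st[k][1]] for k in _STATE_KEYS},
                   present=[False] * t + [True, True] if t else [True, True],
                   entry=t)
        map_of[n] = fresh
        fresh += 1
        return fresh - 1

    def materialize_h(m, t, step_idx):
        """Promote one implicit hydrogen of MTG node m to an explicit node,
        rewriting its history back to step 0."""
        nonlocal fresh
        hv = g.nodes[m]["hcount"]
        if min(hv[: t + 1]) < 1:
            raise StitchError(f"step {step_idx}: cannot reconcile hydrogens "
                              f"on atom {m}")
        for i in range(t + 1):
            hv[i] -= 1
        g.add_node(fresh, element="H",
                   **{k: [0] * (t + 1) for k in _STATE_KEYS},
                   present=[True] * (t + 1), entry=0)
        g.nodes[fresh]["hcount"] = [0] * (t + 1)
        g.add_edge(m, fresh, order=[1.0] * (t + 1))
        fresh += 1
        return fresh - 1

    # step 1 seeds the graph
    its0 = steps[0]
    align0 = {}
    for n in sorted(its0.nodes, key=repr):
        align0[n] = add_atom_vec(its0, n, 0)
    for u, v, d in its0.edges(data=True):
        g.add_edge(align0[u], align0[v], order=[d["order"][0], d["order"][1]])
    alignment.append(dict(align0))

    for t, its in enumerate(steps[1:], start=1):
        step_idx = t + 1
        shared = _map_alignment(g, map_of, its)
        from_maps = shared is not None
        if shared is None:
            shared = _embedding_alignment(g, its, t)
        used_h = set(shared.values())

        # reconcile explicit step hydrogens that the alignment did not cover
        for n in sorted(its.nodes, key=repr):
            if n in shared or not _is_plain_step_h(its, n):
                continue
            heavies = [u for u in its[n]
                       if its.edges[n, u]["order"][0] == 1.0 and u in shared
                       and its.nodes[u]["element"] != "H"]
            if len(heavies) != 1:
                continue  # genuinely new hydrogen (new species / formed later)
            m_heavy = shared[heavies[0]]
            cands = [h for h in _mtg_h_neighbors(g, m_heavy, t) if h not in used_h]
            if cands:
                shared[n] = cands[0]
            else:
                shared[n] = materialize_h(m_heavy, t, step_idx)
            used_h.add(shared[n])

        # verify states on shared atoms (hcount up to spectator slack)
        slack: dict = {}
        for n, m in sorted(shared.items(), key=lambda kv: repr(kv[0])):
            d = g.nodes[m]
            st = _its_states(its, n)
            if not d["present"][t]:
                raise StitchError(f"step {step_idx}: atom {n} maps to a species "
                                  "not present in the intermediate")
            if d["charge"][t] != st["charge"][0] or d["radical"][t] != st["radical"][0]:
                raise StitchError(f"step {step_idx}: atom state disagrees at {n}")
            s = st["hcount"][0] - d["hcount"][t]
            if s:
                free = [h for h in _mtg_h_neighbors(g, m, t) if h not in used_h]
                if s < 0 or s > len(free):
                    raise StitchError(f"step {step_idx}: hydrogen count "
                                      f"disagrees at atom {n}")
                slack[m] = s
        for u, v, d in its.edges(data=True):
            og = d["order"][0]
            if u in shared and v in shared:
                cur = g.edges[shared[u], shared[v]]["order"][t] \
                    if g.has_edge(shared[u], shared[v]) else 0.0
                if cur != og:
                    raise StitchError(f"step {step_idx}: bond order disagrees "
                                      f"on ({u},{v})")
            elif og > 0 and (u in shared) != (v in shared):
                if from_maps:
                    raise StitchError(f"step {step_idx}: new atom {u if v in shared else v} "
                                      "is pre-bonded to the intermediate")

        # carry everything forward by one step
        for _, d in g.nodes(data=True):
            for k in _STATE_KEYS:
                d[k].append(d[k][-1])
            d["present"].append(d["present"][-1])
        for _, _, d in g.edges(data=True):
            d["order"].append(d["order"][-1])
        # place new atoms
        align_t = dict(shared)
        for n in sorted(set(its.nodes) - set(shared), key=repr):
            align_t[n] = add_atom_vec(its, n, t)
        # apply the step
        for n in its.nodes:
            m = align_t[n]
            st = _its_states(its, n)
            g.nodes[m]["charge"][t + 1] = st["charge"][1]
            g.nodes[m]["radical"][t + 1] = st["radical"][1]
            h_after = st["hcount"][1] - slack.get(m, 0)
            if h_after < 0:
                raise StitchError(f"step {step_idx}: hydrogen bookkeeping "
                                  f"underflow at atom {n}")
            g.nodes[m]["hcount"][t + 1] = h_after
        for u, v, d in its.edges(data=True):
            mu, mv = align_t[u], align_t[v]
            og, oh = d["order"]
            if g.has_edge(mu, mv):
                g.edges[mu, mv]["order"][t + 1] = oh
            else:
                g.add_edge(mu, mv, order=[og] * (t + 1) + [oh])
        alignment.append(align_t)

    return MTG(len(steps), g, alignment)


def mtg_slice(m: MTG, t: int) -> nx.Graph:
    """The ITS of step t (1-based), reconstructed from the vectors."""
    if not 1 <= t <= m.steps:
        raise IndexError(f"step index {t} outside 1..{m.steps}")
    nodes = sorted(m.alignment[t - 1].values())
    its = nx.Graph()
    for n in nodes:
        d = m.graph.nodes[n]
        its.add_node(n, element=d["element"],
                     **{k: (d[k][t - 1], d[k][t]) for k in _STATE_KEYS})
    for u, v, d in m.graph.edges(data=True):
        if u in its and v in its:
            a, b = d["order"][t - 1], d["order"][t]
            if a > 0 or b > 0:
                its.add_edge(u, v, order=(a, b))
    return its


def mtg_net(m: MTG) -> nx.Graph:
    """Net reaction ITS: order pairs (o[0], o[n]); transient bonds vanish."""
    its = nx.Graph()
    for n, d in m.graph.nodes(data=True):
        its.add_node(n, element=d["element"],
                     **{k: (d[k][0], d[k][-1]) for k in _STATE_KEYS})
    for u, v, d in m.graph.edges(data=True):
        a, b = d["order"][0], d["order"][-1]
        if a > 0 or b > 0:
            its.add_edge(u, v, order=(a, b))
    return its
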