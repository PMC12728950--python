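"""Chemical reaction network expansion and shortest-route search.

``expand`` grows a network breadth-first: at each generation every rule is
applied (component-covering) to every substrate multiset drawn from the
known species, with the multiset size fixed by the rule's explicit
component count; new species are deduplicated by their canonical
certificate (hydrogen-collapsed).  Hyperedges record rule id, reactant and
product certificate multisets, and the generation of discovery.

``find_route`` searches the hyperedge structure with an A*-flavoured
best-first relaxation: seeds cost 0, a hyperedge becomes applicable once
all its reactants are settled, and a species' cost is the cheapest
``edge_cost + sum(reactant costs)``.  With the default unit edge cost and
the admissible heuristic (0 at the target, else 1) the returned route is
step-count minimal; custom scorers replace edge costs (heuristic clamped
to 0) and may prune steps by returning ``+inf``.
"""

from __future__ import annotations

import heapq
import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import networkx as nx

from . import canon
from . import graphs as G
from . import reactor
from .errors import RouteError, ValidationError
from .rules import RuleSpan

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Hyperedge:
    rule_id: str
    reactants: tuple[str, ...]   # species certificates (sorted multiset)
    products: tuple[str, ...]
    generation: int


@dataclass
class Species:
    certificate: str
    graph: nx.Graph              # hydrogen-collapsed single molecule
    generation: int
    abundant: bool = False

    def smiles(self) -> str:
        from .chemio import write_smiles
        g = self.graph.copy()
        for _, d in g.nodes(data=True):
            d["atom_map"] = None
        return write_smiles(g)


@dataclass
class CRN:
    species: dict[str, Species] = field(default_factory=dict)
    hyperedges: list[Hyperedge] = field(default_factory=list)
    seeds: tuple[str, ...] = ()
    truncated: bool = False

    def to_json(self) -> str:
        import json
        return json.dumps({
            "seeds": list(self.seeds),
            "truncated": self.truncated,
            "species": [{"certificate": c, "smiles": s.smiles(),
                         "generation": s.generation, "abundant": s.abundant}
                        for c, s in sorted(self.species.items())],
            "hyperedges": [{"rule": e.rule_id, "reactants": list(e.reactants),
                            "products": list(e.products), "generation": e.generation}
                           for e in self.hyperedges],
        }, indent=2)

    def to_dot(self) -> str:
        lines = ["digraph crn {"]
        idx = {c: i for i, c in enumerate(sorted(self.species))}
        for c, i in idx.items():
            lines.append(f'  s{i} [label="{self.species[c].smiles()}"];')
        for j, e in enumerate(self.hyperedges):
            lines.append(f'  e{j} [shape=box label="{e.rule_id}"];')
            for r in e.reactants:
                lines.append(f"  s{idx[r]} -> e{j};")
            for p in e.products:
                lines.append(f"  e{j} -> s{idx[p]};")
        lines.append("}")
        return "\n".join(lines) + "\n"


def _canon_species(g: nx.Graph) -> tuple[str, nx.Graph]:
    coll = G.collapse_hydrogens(g)
    return canon.certificate(coll, G.mol_node_label, G.order_label), coll


def _register(crn: CRN, g: nx.Graph, generation: int, abundant: bool = False) -> str:
    cert, coll = _canon_species(g)
    if cert not in crn.species:
        crn.species[cert] = Species(cert, coll, generation, abundant)
    return cert


def _rule_arity(rule: RuleSpan) -> int:
    skip = set().union(*rule.implicit) if rule.implicit else set()
    sub = rule.left.subgraph([n for n in rule.left.nodes if n not in skip])
    return nx.number_connected_components(sub)


def expand(seeds: Sequence[nx.Graph], rules: Sequence[RuleSpan], generations: int,
           cap_per_generation: int = 10000,
           abundant: Iterable[int] = ()) -> CRN:
    """Breadth-first closure of the seed species under the rule library.

    ``abundant`` marks seed indices (e.g. water, acids) that are treated as
    freely available; this only affects route costing downstream, the
    expansion itself never consumes species.
    """
    if generations < 0:
        raise ValidationError("generations must be >= 0")
    crn = CRN()
    abundant = set(abundant)
    seed_certs = []
    for i, g in enumerate(seeds):
        seed_certs.append(_register(crn, g, 0, abundant=i in abundant))
    crn.seeds = tuple(sorted(set(seed_certs)))

    tried: set[tuple] = set()
    for gen in range(1, generations + 1):
        known = sorted(crn.species)
        new_edges = 0
        fresh: list[tuple[str, nx.Graph]] = []
        for rule in rules:
            arity = _rule_arity(rule)
            for combo in itertools.combinations_with_replacement(known, arity):
                key = (rule.rule_id, combo)
                if key in tried:
                    continue
                tried.add(key)
                substrate = G.disjoint_union([crn.species[c].graph for c in combo])
                outcome = reactor.apply(rule, substrate)
                crn.truncated = crn.truncated or outcome.truncated
                for res in outcome:
                    prods = tuple(sorted(
                        _canon_species(c)[0]
                        for c in G.component_subgraphs(res.products)))
                    edge = Hyperedge(rule.rule_id, tuple(sorted(combo)), prods, gen)
                    if edge in crn.hyperedges:
                        continue
                    crn.hyperedges.append(edge)
                    new_edges += 1
                    for comp in G.component_subgraphs(res.products):
                        fresh.append((_canon_species(comp)[0], comp))
                    if new_edges > cap_per_generation:
                        crn.truncated = True
                        break
                if new_edges > cap_per_generation:
                    break
            if new_edges > cap_per_generation:
                break
        for cert, comp in fresh:
            if cert not in crn.species:
                _register(crn, comp, gen)
        if new_edges > cap_per_generation:
            break
    return crn


# ---------------------------------------------------------------------------
# route search
# ---------------------------------------------------------------------------

@dataclass
class Route:
    steps: list[Hyperedge]
    target: str
    cost: float
    sources: tuple[str, ...] = ()


_SCORERS: dict[str, Callable] = {}


def register_scorer(name: str, fn: Callable[[Hyperedge], float]) -> None:
    """Register a step-cost function: hyperedge -> non-negative cost or +inf
    (prune)."""
    _SCORERS[name] = fn


def _resolve_scorer(scorer):
    if scorer is None:
        return None
    if callable(scorer):
        return scorer
    return _SCORERS[scorer]


def find_route(crn: CRN, target: nx.Graph | str,
               scorer: Callable[[Hyperedge], float] | str | None = None) -> Route | None:
    """Cheapest derivation of ``target`` from the seeds within ``crn``.

    A*-style best-first relaxation over species: the priority of a species
    is g + h with h = 0 for the target and 1 otherwise under unit costs
    (admissible), and h = 0 under a custom scorer.  Ties break on the
    lexicographic species certificate.  Returns None when the target is
    not derivable within the expanded horizon.
    """
    tcert = target if isinstance(target, str) else _canon_species(target)[0]
    fn = _resolve_scorer(scorer)

    if tcert in crn.seeds:
        return Route([], tcert, 0.0, (tcert,))

    edge_cost: dict[int, float] = {}
    for i, e in enumerate(crn.hyperedges):
        c = 1.0 if fn is None else fn(e)
        if c is None or (not math.isinf(c) and c < 0):
            raise RouteError(f"scorer returned invalid cost {c!r} for {e.rule_id}")
        edge_cost[i] = c

    by_reactant: dict[str, list[int]] = {}
    for i, e in enumerate(crn.hyperedges):
        for r in set(e.reactants):
            by_reactant.setdefault(r, []).append(i)

    gscore: dict[str, float] = {c: 0.0 for c in crn.seeds}
    settled: set[str] = set()
    best_edge: dict[str, int] = {}
    heap: list[tuple[float, str]] = []

    def h(cert: str) -> float:
        if fn is not None:
            return 0.0
        return 0.0 if cert == tcert else 1.0

    for c in crn.seeds:
        heapq.heappush(heap, (h(c), c))

    while heap:
        f, cert = heapq.heappop(heap)
        if cert in settled:
            continue
        if f > gscore.get(cert, math.inf) + h(cert):
            continue
        settled.add(cert)
        if cert == tcert:
            break
        for i in by_reactant.get(cert, []):
            e = crn.hyperedges[i]
            if math.isinf(edge_cost[i]):
                continue
            if any(r not in settled for r in e.reactants):
                continue
            base = edge_cost[i] + sum(gscore[r] for r in e.reactants)
            for p in e.products:
                if base < gscore.get(p, math.inf):
                    gscore[p] = base
                    best_edge[p] = i
                    heapq.heappush(heap, (base + h(p), p))

    if tcert not in settled:
        log.info("target not reachable within the expanded horizon "
                 "(%d species, %d hyperedges)", len(crn.species), len(crn.hyperedges))
        return None

    # backtrack the derivation tree
    steps: list[Hyperedge] = []
    seen_edges: set[int] = set()
    sources: set[str] = set()

    def collect(cert: str) -> None:
        if cert in crn.seeds:
            sources.add(cert)
            return
        i = best_edge[cert]
        if i in seen_edges:
            return
        seen_edges.add(i)
        for r in crn.hyperedges[i].reactants:
            collect(r)
        steps.append(crn.hyperedges[i])

    collect(tcert)
    return Route(steps, tcert, gscore[tcert], tuple(sorted(sources)))


def search_route(seeds: Sequence[nx.Graph], rules: Sequence[RuleSpan],
                 target: nx.Graph, max_generations: int = 6,
                 scorer=None, cap_per_generation: int = 10000,
                 abundant: Iterable[int] = ()) -> Route | None:
    """Lazy driver: expand generation by generation until the target appears
    (then one search) or the depth limit is reached."""
    tcert = _canon_species(target)[0]
    for gens in range(max_generations + 1):
        crn = expand(seeds, rules, gens, cap_per_generation, abundant)
        if tcert in crn.species:
            return find_route(crn, tcert, scorer)
    log.info("target not found within %d generations", max_generations)
    return None
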