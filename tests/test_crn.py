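"""CRN expansion, route search, and scorers."""

import math

import networkx as nx
import pytest

import rxngraph as rg
from rxngraph.crn import _canon_species
from rxngraph.errors import RouteError
from rxngraph.fixtures import (nitrophenol_rules, nitrophenol_seeds,
                               route_instance, P_NITROPHENOL_SMILES)


@pytest.fixture(scope="module")
def nitro_crn():
    seeds, abundant = nitrophenol_seeds()
    return rg.expand(seeds, list(nitrophenol_rules().values()), 3,
                     abundant=abundant)


class TestExpand:
    def test_zero_generations_is_just_seeds(self):
        seeds, _ = nitrophenol_seeds()
        net = rg.expand(seeds, list(nitrophenol_rules().values()), 0)
        assert len(net.species) == 4 and net.hyperedges == []

    def test_nitrophenol_para_path_present(self, nitro_crn):
        para_intermediate = rg.parse_smiles("Clc1ccc(cc1)[N+](=O)[O-]")
        target = rg.parse_smiles(P_NITROPHENOL_SMILES)
        assert _canon_species(para_intermediate)[0] in nitro_crn.species
        assert _canon_species(target)[0] in nitro_crn.species

    def test_meta_byproduct_path_present(self, nitro_crn):
        meta = rg.parse_smiles("Clc1cccc(c1)[N+](=O)[O-]")
        assert _canon_species(meta)[0] in nitro_crn.species
        assert any(e.rule_id == "chlorination_meta_to_nitro"
                   for e in nitro_crn.hyperedges)

    def test_expansion_is_deterministic(self):
        seeds, abundant = nitrophenol_seeds()
        rules = list(nitrophenol_rules().values())
        a = rg.expand(seeds, rules, 2, abundant=abundant)
        b = rg.expand(seeds, rules, 2, abundant=abundant)
        assert sorted(a.species) == sorted(b.species)
        assert a.hyperedges == b.hyperedges

    def test_species_grow_monotonically(self):
        seeds, abundant = nitrophenol_seeds()
        rules = list(nitrophenol_rules().values())
        prev: set = set()
        for gens in range(3):
            cur = set(rg.expand(seeds, rules, gens, abundant=abundant).species)
            assert prev <= cur
            prev = cur

    def test_hyperedge_generations_are_causal(self, nitro_crn):
        for e in nitro_crn.hyperedges:
            for r in e.reactants:
                assert nitro_crn.species[r].generation < e.generation

    def test_reachability_soundness(self, nitro_crn):
        """Every hyperedge replays through the reactor."""
        from rxngraph import graphs as G
        rules = nitrophenol_rules()
        for e in nitro_crn.hyperedges:
            sub = G.disjoint_union([nitro_crn.species[c].graph for c in e.reactants])
            outs = {tuple(sorted(_canon_species(c)[0]
                                 for c in G.component_subgraphs(r.products)))
                    for r in rg.apply(rules[e.rule_id], sub)}
            assert tuple(sorted(e.products)) in outs


class TestFindRoute:
    def test_target_in_seeds_is_empty_route(self, nitro_crn):
        r = rg.find_route(nitro_crn, rg.parse_smiles("c1ccccc1"))
        assert r.cost == 0 and r.steps == []

    def test_three_step_route_to_p_nitrophenol(self, nitro_crn):
        r = rg.find_route(nitro_crn, rg.parse_smiles(P_NITROPHENOL_SMILES))
        assert r.cost == 3
        assert [s.rule_id for s in r.steps] == [
            "chlorination_benzene", "nitration_para_to_cl",
            "hydrolysis_aryl_chloride"]

    def test_unreachable_target_returns_none(self, nitro_crn):
        assert rg.find_route(nitro_crn, rg.parse_smiles("CCCCBr")) is None

    def test_route_costs_match_bfs_oracle(self):
        for seed in range(15):
            inst = route_instance(seed)
            dg = nx.DiGraph(inst["edges"])
            try:
                bfs = nx.shortest_path_length(dg, inst["start"], inst["goal"])
            except (nx.NetworkXNoPath, nx.NodeNotFound):
                bfs = None
            crn = rg.expand(inst["seeds"], inst["rules"], 5,
                            abundant=inst["abundant"])
            route = rg.find_route(crn, inst["target"])
            assert (route.cost if route else None) == bfs

    def test_lazy_search_route(self):
        inst = route_instance(3)
        route = rg.search_route(inst["seeds"], inst["rules"], inst["target"],
                                max_generations=5)
        dg = nx.DiGraph(inst["edges"])
        try:
            bfs = nx.shortest_path_length(dg, inst["start"], inst["goal"])
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            bfs = None
        assert (route.cost if route else None) == bfs


class TestScorers:
    def test_constant_scorer_reproduces_default(self, nitro_crn):
        target = rg.parse_smiles(P_NITROPHENOL_SMILES)
        default = rg.find_route(nitro_crn, target)
        const = rg.find_route(nitro_crn, target, scorer=lambda e: 1.0)
        assert const.cost == default.cost

    def test_pruning_infeasible_nitration_of_phenol(self, nitro_crn):
        target = rg.parse_smiles(P_NITROPHENOL_SMILES)
        prune = lambda e: math.inf if e.rule_id == "nitration_of_phenol" else 1.0
        r = rg.find_route(nitro_crn, target, scorer=prune)
        assert r is not None
        assert all(s.rule_id != "nitration_of_phenol" for s in r.steps)

    def test_pruning_never_yields_cheaper_routes(self, nitro_crn):
        target = rg.parse_smiles(P_NITROPHENOL_SMILES)
        base = rg.find_route(nitro_crn, target).cost
        prune = lambda e: math.inf if "meta" in e.rule_id else 1.0
        assert rg.find_route(nitro_crn, target, scorer=prune).cost >= base

    def test_registered_scorer_by_name(self, nitro_crn):
        rg.register_scorer("unit", lambda e: 1.0)
        r = rg.find_route(nitro_crn, rg.parse_smiles(P_NITROPHENOL_SMILES),
                          scorer="unit")
        assert r.cost == 3

    def test_negative_cost_is_a_contract_error(self, nitro_crn):
        with pytest.raises(RouteError):
            rg.find_route(nitro_crn, rg.parse_smiles(P_NITROPHENOL_SMILES),
                          scorer=lambda e: -1.0)


class TestSerialization:
    def test_json_and_dot(self, nitro_crn):
        import json
        data = json.loads(nitro_crn.to_json())
        assert len(data["species"]) == len(nitro_crn.species)
        assert nitro_crn.to_dot().startswith("digraph crn {")
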