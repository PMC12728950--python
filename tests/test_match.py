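"""Subgraph matching, SING index, and clustering."""

import random

import networkx as nx
import pytest
from networkx.algorithms import isomorphism as nxiso

import rxngraph as rg
from rxngraph import graphs as G
from rxngraph.errors import ValidationError
from rxngraph.match import (batch_cluster, cluster, find_embeddings, is_isomorphic,
                            partition_scores, sing_build, sing_query)

NM = nxiso.categorical_node_match("label", None)
EM = nxiso.categorical_edge_match("label", None)


def _uniform(g):
    nx.set_node_attributes(g, "C", "label")
    nx.set_edge_attributes(g, 1.0, "label")
    return g


def _random_graph(rng, n_max=9, labels="AB"):
    n = rng.randint(1, n_max)
    g = nx.Graph()
    for i in range(n):
        g.add_node(i, label=rng.choice(labels))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.35:
                g.add_edge(i, j, label=rng.choice("xy"))
    return g


class TestIsIsomorphic:
    def test_random_relabeling_is_isomorphic(self):
        rng = random.Random(0)
        g = _random_graph(rng)
        perm = dict(zip(g.nodes, rng.sample(list(g.nodes), g.number_of_nodes())))
        assert is_isomorphic(g, nx.relabel_nodes(g, perm))

    def test_c6_vs_two_triangles(self):
        assert not is_isomorphic(_uniform(nx.cycle_graph(6)),
                                 _uniform(nx.disjoint_union(nx.cycle_graph(3),
                                                            nx.cycle_graph(3))))

    def test_agreement_with_vf2_on_random_pairs(self):
        rng = random.Random(13)
        for _ in range(300):
            a, b = _random_graph(rng), _random_graph(rng)
            expected = nx.is_isomorphic(a, b, node_match=NM, edge_match=EM)
            assert is_isomorphic(a, b) == expected


class TestFindEmbeddings:
    def test_single_edge_into_triangle(self):
        pat = _uniform(nx.path_graph(2))
        tri = _uniform(nx.cycle_graph(3))
        assert len(find_embeddings(pat, tri)) == 6

    def test_pattern_larger_than_host(self):
        assert find_embeddings(_uniform(nx.path_graph(5)),
                               _uniform(nx.path_graph(3))) == []

    def test_diels_alder_left_pattern_symmetries(self, diels_its):
        rule = rg.extract_rule(rg.reaction_center(diels_its))
        host = G.disjoint_union([rg.parse_smiles("C=CC=C"), rg.parse_smiles("C=C")])
        from rxngraph.rules import _rule_node_label
        embs = find_embeddings(rule.left, host, node_label=_rule_node_label,
                               edge_label=lambda d: d["order"])
        assert len(embs) == 4  # 2 diene x 2 dienophile symmetries

    def test_complete_against_vf2_monomorphisms(self):
        rng = random.Random(21)
        for _ in range(100):
            host = _random_graph(rng, 8)
            pat = _random_graph(rng, 4)
            got = {tuple(sorted(m.items())) for m in find_embeddings(pat, host)}
            gm = nxiso.GraphMatcher(host, pat, node_match=NM, edge_match=EM)
            want = {tuple(sorted((pv, hv) for hv, pv in m.items()))
                    for m in gm.subgraph_monomorphisms_iter()}
            assert got == want

    def test_induced_mode_respects_non_edges(self):
        pat = _uniform(nx.path_graph(3))       # no 0-2 edge
        tri = _uniform(nx.cycle_graph(3))
        assert find_embeddings(pat, tri, induced=True) == []
        assert len(find_embeddings(pat, tri, induced=False)) == 6

    def test_deterministic_order(self):
        rng = random.Random(2)
        host = _random_graph(rng, 8)
        pat = _random_graph(rng, 3)
        assert find_embeddings(pat, host) == find_embeddings(pat, host)

    def test_closed_under_host_automorphism(self):
        # host = labeled star; swapping equivalent leaves maps embeddings to embeddings
        host = nx.Graph()
        host.add_node(0, label="C")
        for i in (1, 2, 3):
            host.add_node(i, label="O")
            host.add_edge(0, i, label=1.0)
        pat = nx.Graph()
        pat.add_node("a", label="C")
        pat.add_node("b", label="O")
        pat.add_edge("a", "b", label=1.0)
        images = {m["b"] for m in find_embeddings(pat, host)}
        assert images == {1, 2, 3}


class TestSing:
    def test_empty_host_set(self):
        idx = sing_build({})
        assert sing_query(_uniform(nx.path_graph(2)), idx) == {}

    def test_multigraph_refused(self):
        with pytest.raises(ValidationError):
            sing_build({"m": nx.MultiGraph()})

    def test_self_containment(self, corpus_records):
        hosts = {}
        for rec in corpus_records[:30]:
            for comp in G.component_subgraphs(rec.reactants):
                hosts[len(hosts)] = G.labeled_copy(G.collapse_hydrogens(comp),
                                                   G.mol_node_label, G.order_label)
        idx = sing_build(hosts, depth=3)
        for hid in list(hosts)[:10]:
            res = sing_query(hosts[hid], idx)
            assert hid in res and len(res[hid]) >= 1

    def test_absent_label_gives_empty(self, corpus_records):
        hosts = {0: G.labeled_copy(rg.parse_smiles("CCO"), G.mol_node_label,
                                   G.order_label)}
        idx = sing_build(hosts)
        pat = nx.Graph()
        pat.add_node(0, label=("Xe", 0, 0, 0))
        assert sing_query(pat, idx) == {}

    def test_equivalence_with_naive_sweep(self):
        rng = random.Random(31)
        hosts = {i: _random_graph(rng, 10) for i in range(40)}
        idx = sing_build(hosts, depth=3)
        for _ in range(40):
            pat = _random_graph(rng, 4)
            if not nx.is_connected(pat):
                continue
            naive = {h: find_embeddings(pat, g) for h, g in hosts.items()}
            naive = {h: e for h, e in naive.items() if e}
            assert sing_query(pat, idx) == naive

    def test_filter_soundness_per_node(self):
        # every host node an embedding uses carries all the pattern node features
        from rxngraph.match import _node_features
        rng = random.Random(41)
        for _ in range(30):
            host = _random_graph(rng, 9)
            pat = _random_graph(rng, 4)
            pf = _node_features(pat, 3, lambda d: d.get("label"), lambda d: d.get("label"))
            hf = _node_features(host, 3, lambda d: d.get("label"), lambda d: d.get("label"))
            for m in find_embeddings(pat, host):
                for pv, hv in m.items():
                    assert pf[pv] <= hf[hv]

    def test_depth_zero_is_label_filtering(self):
        hosts = {0: _uniform(nx.path_graph(3))}
        idx = sing_build(hosts, depth=0)
        assert set(idx.inverted) == {("C",)} or len(idx.inverted) == 1


class TestClustering:
    def test_single_graph(self):
        part = cluster({0: _uniform(nx.path_graph(2))})
        assert part.n_clusters == 1

    def test_partition_independent_of_wl_iterations(self, corpus, corpus_records):
        centers = {i: G.labeled_copy(rg.reaction_center(rg.build_its(r)),
                                     G.its_core_node_label, G.pair_label)
                   for i, r in enumerate(corpus_records)}
        parts = [cluster(centers, k).labels for k in (0, 1, 4)]
        assert parts[0] == parts[1] == parts[2]

    def test_recovers_generator_labels(self, corpus, corpus_records):
        centers = {i: G.labeled_copy(rg.reaction_center(rg.build_its(r)),
                                     G.its_core_node_label, G.pair_label)
                   for i, r in enumerate(corpus_records)}
        part = cluster(centers, 1)
        truth = {i: corpus.reactions[i][1] for i in centers}
        scores = partition_scores(part.labels, truth)
        assert scores == {"purity": 1.0, "ari": 1.0, "nmi": 1.0}

    def test_batch_equals_unbatched_for_random_batch_sizes(self, corpus_records):
        rng = random.Random(9)
        centers = {i: G.labeled_copy(rg.reaction_center(rg.build_its(r)),
                                     G.its_core_node_label, G.pair_label)
                   for i, r in enumerate(corpus_records[:40])}
        ref = cluster(centers).labels
        for bs in (1, 3, 7, 40, 1000):
            assert batch_cluster(centers, batch_size=bs).labels == ref
        for _ in range(5):
            bs = rng.randint(1, 50)
            assert batch_cluster(centers, batch_size=bs).labels == ref

    def test_batch_size_validation(self):
        with pytest.raises(ValidationError):
            batch_cluster({}, batch_size=0)
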