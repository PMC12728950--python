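"""Rule extraction, inversion, and (partial) composition."""

import networkx as nx
import pytest

import rxngraph as rg
from rxngraph import graphs as G
from rxngraph.errors import RuleError
from rxngraph.rules import element_multisets

from conftest import ensemble_certs


class TestExtractRule:
    def test_diels_alder_span_counts(self, diels_its):
        rule = rg.extract_rule(rg.reaction_center(diels_its))
        assert (rule.left.number_of_nodes(), rule.left.number_of_edges()) == (6, 4)
        assert (rule.right.number_of_nodes(), rule.right.number_of_edges()) == (6, 6)
        assert (rule.context.number_of_nodes(), rule.context.number_of_edges()) == (6, 0)

    def test_hydrogenation_span(self, hydrogenation_rule):
        r = hydrogenation_rule
        left_orders = sorted(d["order"] for _, _, d in r.left.edges(data=True))
        right_orders = sorted(d["order"] for _, _, d in r.right.edges(data=True))
        assert left_orders == [1.0, 2.0]        # H-H and C=C
        assert right_orders == [1.0, 1.0, 1.0]  # C-C and 2x C-H
        assert r.context.number_of_nodes() == 4

    def test_radius_one_is_node_superset_of_radius_zero(self, corpus_records):
        for rec in corpus_records[:15]:
            its = rg.build_its(rec)
            r0 = rg.extract_rule(rg.reaction_center(its, 0))
            r1 = rg.extract_rule(rg.reaction_center(its, 1))
            assert set(r0.left.nodes) <= set(r1.left.nodes)

    def test_empty_center_refused(self):
        with pytest.raises(RuleError):
            rg.extract_rule(nx.Graph())

    def test_rule_id_is_content_addressed(self, diels_its):
        a = rg.extract_rule(rg.reaction_center(diels_its))
        b = rg.extract_rule(rg.reaction_center(diels_its))
        assert a.rule_id == b.rule_id and a.rule_id.startswith("r_")


class TestInvertRule:
    def test_involution(self, corpus_records):
        for rec in corpus_records[:20]:
            rule = rg.extract_rule(rg.reaction_center(rg.build_its(rec)))
            back = rg.invert_rule(rg.invert_rule(rule))
            assert back.certificate() == rule.certificate()

    def test_inverted_hydrogenation_dehydrogenates(self, hydrogenation_rule):
        res = rg.apply(rg.invert_rule(hydrogenation_rule), rg.parse_smiles("CC"))
        assert [r.product_smiles() for r in res] == ["C=C.[H][H]"]

    def test_identity_rule_is_self_inverse(self):
        rule = rg.identity_rule(rg.parse_smiles("C"), "id")
        assert rg.invert_rule(rule).certificate() == rule.certificate()


class TestCompose:
    def test_sequential_hydrogenations(self, alkyne_rule, hydrogenation_rule):
        comps = rg.compose(alkyne_rule, hydrogenation_rule)
        assert len(comps) == 1
        # acetylene + 2 H2 -> ethane under the composite
        sub = G.disjoint_union([rg.parse_smiles("C#C"), rg.parse_smiles("[H][H]"),
                                rg.parse_smiles("[H][H]")])
        res = rg.apply(comps[0], sub)
        assert [r.product_smiles() for r in res] == ["CC"]

    def test_compose_with_identity_returns_original(self, hydrogenation_rule):
        ident = rg.identity_rule(rg.parse_smiles("[CH4:1]"), "idC")
        comps = rg.compose(hydrogenation_rule, ident)
        assert len(comps) == 1
        assert comps[0].changed_edges() == hydrogenation_rule.changed_edges()

    def test_composite_matches_sequential_application(self, alkyne_rule,
                                                      hydrogenation_rule):
        comps = rg.compose(alkyne_rule, hydrogenation_rule)
        sub = G.disjoint_union([rg.parse_smiles("C#C"), rg.parse_smiles("[H][H]"),
                                rg.parse_smiles("[H][H]")])
        composite_out = {r.product_certificates for r in rg.apply(comps[0], sub)}
        step1 = rg.apply(alkyne_rule, G.disjoint_union(
            [rg.parse_smiles("C#C"), rg.parse_smiles("[H][H]")]))
        seq_out = set()
        for r1 in step1:
            inter = G.collapse_hydrogens(r1.products)
            sub2 = G.disjoint_union(G.component_subgraphs(inter)
                                    + [rg.parse_smiles("[H][H]")])
            for r2 in rg.apply(hydrogenation_rule, sub2):
                seq_out.add(r2.product_certificates)
        assert composite_out == seq_out

    def test_atom_conservation_of_composites(self, alkyne_rule, hydrogenation_rule):
        for c in rg.compose(alkyne_rule, hydrogenation_rule):
            left, right = element_multisets(c)
            assert left == right

    def test_associativity_via_product_sets(self, alkyne_rule, hydrogenation_rule):
        # ((alkyne . alkene) . alkene-inverse) vs (alkyne . (alkene . alkene-inv))
        inv = rg.invert_rule(hydrogenation_rule)
        left = [x for c in rg.compose(alkyne_rule, hydrogenation_rule)
                for x in rg.compose(c, inv)]
        right = [x for c in rg.compose(hydrogenation_rule, inv)
                 for x in rg.compose(alkyne_rule, c)]
        sub = G.disjoint_union([rg.parse_smiles("C#C"), rg.parse_smiles("[H][H]"),
                                rg.parse_smiles("[H][H]")])
        prods = lambda rules: {r.product_certificates
                               for c in rules for r in rg.apply(c, sub)}
        assert prods(left) == prods(right)


class TestPartialCompose:
    def test_but2ene_direct_hydrogenation(self, hydrogenation_rule):
        ident = rg.fixtures.worked_examples()["but2ene_identity_rule"]
        comps = rg.partial_compose(ident, hydrogenation_rule)
        direct = [c for c in comps if c.implicit
                  and nx.number_connected_components(c.left) == 2
                  and c.left.number_of_nodes() == 6]
        assert len(direct) == 1
        res = rg.apply(direct[0], rg.parse_smiles("CC=CC"))
        assert [r.product_smiles() for r in res] == ["CCCC"]

    def test_disjoint_rules_include_union_composite(self):
        a = rg.identity_rule(rg.parse_smiles("C"), "idC")
        b = rg.identity_rule(rg.parse_smiles("O"), "idO")
        comps = rg.partial_compose(a, b)
        assert any(set(n for _, n in
                       ((d["element"], d["element"]) for _, d in c.left.nodes(data=True)))
                   == {"C", "O"} and not c.implicit for c in comps)

    def test_implicit_reagent_preserves_mass_bookkeeping(self, hydrogenation_rule):
        ident = rg.identity_rule(rg.parse_smiles("C=C"), "idCC")
        comps = rg.partial_compose(ident, hydrogenation_rule)
        for c in comps:
            left, right = element_multisets(c)
            assert left == right  # implicit atoms still counted on both sides

    def test_implicit_composite_reachable_by_explicit_route(self, hydrogenation_rule):
        ident = rg.fixtures.worked_examples()["but2ene_identity_rule"]
        direct = [c for c in rg.partial_compose(ident, hydrogenation_rule)
                  if c.implicit and nx.number_connected_components(c.left) == 2][0]
        implicit_out = {r.product_certificates[0]
                        for r in rg.apply(direct, rg.parse_smiles("CC=CC"))}
        explicit_sub = G.disjoint_union([rg.parse_smiles("CC=CC"),
                                         rg.parse_smiles("[H][H]")])
        explicit_out = {c for r in rg.apply(hydrogenation_rule, explicit_sub)
                        for c in r.product_certificates}
        assert implicit_out <= explicit_out


class TestProjectionRoundTrip:
    def test_rule_recovers_reaction_on_corpus_sample(self, corpus_records):
        from rxngraph.its import hydrogen_completion
        for rec in corpus_records[:25]:
            rule = rg.extract_rule(rg.reaction_center(rg.build_its(rec)))
            full = hydrogen_completion(rec)
            want = ensemble_certs(full.products)
            got = {r.product_certificates for r in rg.apply(rule, full.reactants)}
            assert want in got
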