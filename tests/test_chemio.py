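"""Reaction SMILES parsing/writing and the GML rule dialect."""

import pytest

import rxngraph as rg
from rxngraph import graphs as G
from rxngraph.errors import ParseError, SchemaError, ValidationError

from conftest import its_isomorphic


class TestParseReactionSmiles:
    def test_diels_alder_example(self, diels_record):
        r = diels_record
        assert r.reactants.number_of_nodes() == 6
        assert r.products.number_of_nodes() == 6
        assert max(d["component"] for _, d in r.reactants.nodes(data=True)) == 1
        assert max(d["component"] for _, d in r.products.nodes(data=True)) == 0
        assert set(r.aam()) == {1, 2, 3, 4, 5, 6}
        assert r.is_balanced()

    def test_identity_reaction(self):
        r = rg.parse_reaction_smiles("[CH4:1]>>[CH4:1]")
        assert r.aam() == {1: (0, 0)}
        assert r.is_balanced()

    def test_unbalanced_record_is_flagged(self):
        r = rg.parse_reaction_smiles("[CH3:1][OH:2]>>[CH4:1]")
        assert not r.is_balanced()
        assert any("map 2" in s for s in r.unmapped())

    def test_agents_are_discarded_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            r = rg.parse_reaction_smiles("[CH4:1]>O>[CH4:1]")
        assert r.is_balanced()
        assert any("agents" in rec.message for rec in caplog.records)

    def test_stereo_tokens_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            rg.parse_smiles("C/C=C/C")
        assert any("stereo" in rec.message for rec in caplog.records)

    def test_unparsable_smiles_names_component(self):
        with pytest.raises(ParseError, match="xyz"):
            rg.parse_reaction_smiles("C.xyz>>C")

    def test_duplicate_map_within_side_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            rg.parse_reaction_smiles("[CH3:1][CH3:1]>>[CH3:1][CH3:2]")

    def test_aromatic_ring_perceived_as_order_15(self):
        g = rg.parse_smiles("C1=CC=CC=C1")  # kekulized input
        orders = {d["order"] for _, _, d in g.edges(data=True)}
        assert orders == {1.5}


class TestWriteReactionSmiles:
    def test_single_atom_with_map(self):
        g = rg.parse_smiles("[CH4:7]")
        assert rg.write_smiles(g) == "[CH4:7]"

    def test_diels_alder_round_trip(self, diels_record):
        text = rg.write_reaction_smiles(diels_record)
        again = rg.parse_reaction_smiles(text)
        assert its_isomorphic(rg.build_its(diels_record), rg.build_its(again))

    def test_round_trip_on_corpus(self, corpus_records):
        for rec in corpus_records:
            again = rg.parse_reaction_smiles(rg.write_reaction_smiles(rec))
            assert its_isomorphic(rg.build_its(rec), rg.build_its(again))

    def test_writing_is_deterministic(self, corpus_records):
        for rec in corpus_records[:10]:
            assert rg.write_reaction_smiles(rec) == rg.write_reaction_smiles(rec)


class TestGmlRules:
    def test_diels_alder_section_counts(self, diels_its):
        rule = rg.extract_rule(rg.reaction_center(diels_its))
        text = rg.rule_to_gml(rule)
        lines = text.splitlines()
        ctx = lines[lines.index("  context ["):lines.index("  right [")]
        left = lines[lines.index("  left ["):lines.index("  context [")]
        right = lines[lines.index("  right ["):]
        assert sum("node [" in ln for ln in ctx) == 6
        assert sum("edge [" in ln for ln in left) == 4
        assert sum("edge [" in ln for ln in right) == 6

    def test_identity_rule_has_empty_left_right(self):
        rule = rg.identity_rule(rg.parse_smiles("C"), "id")
        text = rg.rule_to_gml(rule)
        assert "  left [\n  ]" in text and "  right [\n  ]" in text

    def test_minimal_context_only_rule(self):
        rule = rg.gml_to_rule('rule [ context [ node [ id 1 label "C" ] ] ]')
        assert rule.context.number_of_nodes() == 1
        assert not rule.changed_edges()

    def test_round_trip_identity_up_to_isomorphism(self, corpus_records):
        for rec in corpus_records[:40]:
            rule = rg.extract_rule(rg.reaction_center(rg.build_its(rec)))
            back = rg.gml_to_rule(rg.rule_to_gml(rule))
            assert back.certificate() == rule.certificate()

    def test_hydrogenation_rule_from_gml(self):
        text = """rule [
          ruleID "h2"
          left [
            edge [ source 1 target 2 label "=" ]
            edge [ source 3 target 4 label "-" ]
          ]
          context [
            node [ id 1 label "C" ] node [ id 2 label "C" ]
            node [ id 3 label "H" ] node [ id 4 label "H" ]
          ]
          right [
            edge [ source 1 target 2 label "-" ]
            edge [ source 1 target 3 label "-" ]
            edge [ source 2 target 4 label "-" ]
          ]
        ]"""
        rule = rg.gml_to_rule(text)
        assert rule.changed_edges() == {(1, 2): (2.0, 1.0), (3, 4): (1.0, 0.0),
                                        (1, 3): (0.0, 1.0), (2, 4): (0.0, 1.0)}

    def test_unknown_bond_label_rejected(self):
        with pytest.raises(SchemaError, match="bond label"):
            rg.gml_to_rule('rule [ context [ node [ id 1 label "C" ] '
                           'node [ id 2 label "C" ] '
                           'edge [ source 1 target 2 label ":=" ] ] ]')

    def test_dangling_edge_endpoint_rejected(self):
        with pytest.raises(SchemaError, match="endpoint"):
            rg.gml_to_rule('rule [ context [ node [ id 1 label "C" ] '
                           'edge [ source 1 target 9 label "-" ] ] ]')

    def test_charged_node_labels_round_trip(self):
        rule = rg.extract_rule(rg.reaction_center(
            rg.its_from_smiles("[CH3:1][Cl:2].[OH-:3]>>[CH3:1][OH:3].[Cl-:2]")))
        text = rg.rule_to_gml(rule)
        assert '"O-"' in text and '"Cl-"' in text
        assert rg.gml_to_rule(text).certificate() == rule.certificate()

    def test_json_export_parses(self, diels_record):
        import json
        data = json.loads(diels_record.to_json())
        assert data["balanced"] and len(data["reactants"]["nodes"]) == 6
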