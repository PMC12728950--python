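import pytest

import rxngraph as rg
from rxngraph import graphs as G


@pytest.fixture(scope="session")
def corpus():
    """Small labeled synthetic corpus shared across the suite."""
    return rg.fixtures.generate(n=80, seed=11)


@pytest.fixture(scope="session")
def corpus_records(corpus):
    return [rg.parse_reaction_smiles(smi) for smi, _ in corpus.reactions]


@pytest.fixture()
def diels_record():
    return rg.parse_reaction_smiles(rg.fixtures.DIELS_ALDER)


@pytest.fixture()
def diels_its(diels_record):
    return rg.build_its(diels_record)


@pytest.fixture()
def hydrogenation_rule():
    its = rg.its_from_smiles(rg.fixtures.ETHENE_HYDROGENATION)
    return rg.extract_rule(rg.reaction_center(its), rule_id="alkene_h2")


@pytest.fixture()
def alkyne_rule():
    its = rg.its_from_smiles(rg.fixtures.ACETYLENE_HYDROGENATION)
    return rg.extract_rule(rg.reaction_center(its), rule_id="alkyne_h2")


def its_isomorphic(a, b):
    return rg.is_isomorphic(a, b, node_label=G.its_node_label, edge_label=G.pair_label)


def ensemble_certs(g):
    return tuple(sorted(rg.molecule_certificate(c) for c in G.component_subgraphs(g)))
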