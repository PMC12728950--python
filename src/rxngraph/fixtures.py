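"""Synthetic reaction corpora and packaged worked examples.

Everything here is generated programmatically so the toolkit is testable
without external data.  The template library spans 25 coarse reaction
classes (additions, eliminations, substitutions, cycloadditions, redox and
condensation steps) whose radius-0 reaction centers are pairwise
non-isomorphic; the corpus generator decorates a template with random
acyclic C/N/O substituents -- attached identically on both sides through
the atom map -- so that every generated reaction is balanced and its
radius-0 center is exactly the template's.

Worked examples packaged for the documentation and the test-suite:
a Diels-Alder cycloaddition, the alkyne/alkene hydrogenation pair (rule
composition), the but-2-ene partial-composition case, a two-step aldol
mechanism, and a nitrophenol route set with positional selectivity encoded
as refined (full-environment) rules.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field

import networkx as nx

from . import graphs as G
from .chemio import ReactionRecord, parse_reaction_smiles, parse_smiles, write_reaction_smiles
from .errors import ValidationError
from .its import build_its, reaction_center
from .rules import RuleSpan, extract_rule, identity_rule

# ---------------------------------------------------------------------------
# template library (mapped reaction SMILES; radius-0 cores pairwise distinct)
# ---------------------------------------------------------------------------

TEMPLATE_REACTIONS: tuple[str, ...] = (
    # hydrogenations / additions to multiple bonds
    "[CH2:1]=[CH2:2].[H:3][H:4]>>[CH2:1]([H:3])[CH2:2][H:4]",
    "[CH:1]#[CH:2].[H:3][H:4]>>[CH:1]([H:3])=[CH:2][H:4]",
    "[CH3:5][C:1](=[O:2])[CH3:6].[H:3][H:4]>>[CH3:5][C:1]([H:3])([O:2][H:4])[CH3:6]",
    "[CH3:5][CH:1]=[N:2][CH3:6].[H:3][H:4]>>[CH3:5][CH:1]([H:3])[N:2]([H:4])[CH3:6]",
    "[CH3:5][C:1]#[N:2].[H:3][H:4]>>[CH3:5][C:1]([H:3])=[N:2][H:4]",
    "[CH2:1]=[CH2:2].[H:3][Cl:4]>>[CH2:1]([H:3])[CH2:2][Cl:4]",
    "[CH2:1]=[CH2:2].[H:3][Br:4]>>[CH2:1]([H:3])[CH2:2][Br:4]",
    "[CH2:1]=[CH2:2].[H:3][O:4][H:5]>>[CH2:1]([H:3])[CH2:2][O:4][H:5]",
    "[CH3:5][CH:1]=[O:2].[H:3][C:4]#[N:6]>>[CH3:5][CH:1]([O:2][H:3])[C:4]#[N:6]",
    # cycloadditions
    "[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
    ">>[CH2:1]1[CH:2]=[CH:3][CH2:4][CH2:5][CH2:6]1",
    "[CH2:1]1[CH:2]=[CH:3][CH2:4][CH2:5][CH2:6]1"
    ">>[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]",
    # substitutions
    "[CH3:1][Cl:2].[OH-:3]>>[CH3:1][OH:3].[Cl-:2]",
    "[CH3:1][Br:2].[OH-:3]>>[CH3:1][OH:3].[Br-:2]",
    "[CH3:1][Cl:2].[N:3]([H:4])([H:5])[H:6]>>[CH3:1][N:3]([H:5])[H:6].[H:4][Cl:2]",
    "[CH3:1][Br:2].[S:3]([H:4])[H:5]>>[CH3:1][S:3][H:5].[H:4][Br:2]",
    "[CH3:1][Br:2].[O:3]([H:4])[H:5]>>[CH3:1][O:3][H:5].[H:4][Br:2]",
    # eliminations / fragmentations
    "[CH3:5][CH:1]([H:7])[CH2:2][Br:3].[OH-:4]"
    ">>[CH3:5][CH:1]=[CH2:2].[Br-:3].[OH:4][H:7]",
    "[CH3:1][C:2](=[O:3])[O:4][H:5]>>[CH3:1][H:5].[O:3]=[C:2]=[O:4]",
    # carbonyl chemistry
    "[CH3:6][C:1](=[O:2])[O:3][CH3:7].[O:4]([H:8])[H:9]"
    ">>[CH3:6][C:1](=[O:2])[O:4][H:8].[O:3]([H:9])[CH3:7]",
    "[CH3:6][C:1](=[O:2])[N:3]([H:10])[CH3:7].[O:4]([H:8])[H:9]"
    ">>[CH3:6][C:1](=[O:2])[O:4][H:8].[N:3]([H:10])([H:9])[CH3:7]",
    "[CH2:1]=[CH2:2].[N:3]([H:4])([H:5])[H:6]"
    ">>[CH2:1]([H:4])[CH2:2][N:3]([H:5])[H:6]",
    "[CH3:1][C:2](=[O:3])[CH2:4][H:5]>>[CH3:1][C:2]([O:3][H:5])=[CH2:4]",
    "[CH3:1][C:2]([O:3][H:8])=[CH2:4].[CH3:5][CH:6]=[O:7]"
    ">>[CH3:1][C:2](=[O:3])[CH2:4][CH:6]([O:7][H:8])[CH3:5]",
    # condensation / isomerization
    "[CH3:6][C:1](=[O:2])[CH3:7].[N:3]([H:4])([H:5])[CH3:8]"
    ">>[CH3:6][C:1](=[N:3][CH3:8])[CH3:7].[O:2]([H:4])[H:5]",
    "[CH2:1]=[CH:2][CH2:3][H:4]>>[CH2:1]([H:4])[CH:2]=[CH2:3]",
)


def template_rules(radius: int = 0) -> list[RuleSpan]:
    """The template library as DPO rules extracted at the given radius."""
    out = []
    for i, smi in enumerate(TEMPLATE_REACTIONS):
        its = build_its(parse_reaction_smiles(smi))
        out.append(extract_rule(reaction_center(its, radius), rule_id=f"t{i:02d}"))
    return out


# ---------------------------------------------------------------------------
# synthetic corpus
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCorpus:
    """Reactions with known generating-template labels."""
    reactions: list[tuple[str, int]]         # (mapped reaction SMILES, label)
    templates: tuple[str, ...]
    seed: int
    decoration: tuple[int, int] = (0, 8)

    def to_tsv(self) -> str:
        return "".join(f"{smi}\t{label}\n" for smi, label in self.reactions)

    def manifest(self) -> str:
        return json.dumps({"seed": self.seed, "n": len(self.reactions),
                           "templates": list(self.templates),
                           "decoration": list(self.decoration)}, indent=2)


_DECOR_ELEMENTS = ("C", "C", "C", "C", "N", "O")  # carbon-rich, valence-legal


def _decorate(record: ReactionRecord, rng: random.Random,
              size_range: tuple[int, int]) -> ReactionRecord:
    """Attach a random acyclic C/N/O tree identically to both sides."""
    reactants = record.reactants.copy()
    products = record.products.copy()
    aam = {d["atom_map"]: n for n, d in reactants.nodes(data=True)}
    pam = {d["atom_map"]: n for n, d in products.nodes(data=True)}
    next_map = max(aam) + 1
    next_r = max(reactants.nodes) + 1
    next_p = max(products.nodes) + 1
    k = rng.randint(*size_range)
    for _ in range(k):
        sites = [m for m in sorted(aam)
                 if reactants.nodes[aam[m]]["element"] != "H"
                 and min(reactants.nodes[aam[m]].get("hcount", 0),
                         products.nodes[pam[m]].get("hcount", 0)) >= 1]
        if not sites:
            break
        anchor = rng.choice(sites)
        element = rng.choice(_DECOR_ELEMENTS)
        hnew = G.DEFAULT_VALENCE[element] - 1
        for side, idx, nid in ((reactants, aam, next_r), (products, pam, next_p)):
            G.add_atom(side, nid, element, hcount=hnew, atom_map=next_map)
            G.add_bond(side, nid, idx[anchor], 1.0)
            side.nodes[idx[anchor]]["hcount"] -= 1
            idx[next_map] = nid
        next_map += 1
        next_r += 1
        next_p += 1
    G.assign_components(reactants)
    G.assign_components(products)
    return ReactionRecord(reactants, products)


def generate(templates: tuple[str, ...] | None = None, n: int = 500, seed: int = 42,
             decoration: tuple[int, int] = (0, 8)) -> SyntheticCorpus:
    """Generate ``n`` decorated, atom-mapped reactions with template labels.

    Templates are used round-robin so that every class is represented;
    the output is fully reproducible per seed.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    templates = tuple(templates if templates is not None else TEMPLATE_REACTIONS)
    if not templates:
        raise ValidationError("template list must be non-empty")
    from .its import hydrogen_completion
    rng = random.Random(seed)
    parsed = [hydrogen_completion(parse_reaction_smiles(s)) for s in templates]
    reactions = []
    for i in range(n):
        label = i % len(templates)
        for _ in range(10):  # resample on the (rare) unserializable decoration
            try:
                rec = _decorate(parsed[label], rng, decoration)
                reactions.append((write_reaction_smiles(rec), label))
                break
            except Exception:
                continue
        else:
            raise ValidationError(f"could not decorate template {label}")
    return SyntheticCorpus(reactions, templates, seed, decoration)


def corpus_centers(corpus: SyntheticCorpus, radius: int = 0) -> dict[int, nx.Graph]:
    """Radius-r reaction-center ITS graphs of every corpus reaction."""
    return {i: reaction_center(build_its(parse_reaction_smiles(smi)), radius)
            for i, (smi, _) in enumerate(corpus.reactions)}


# ---------------------------------------------------------------------------
# worked examples
# ---------------------------------------------------------------------------

DIELS_ALDER = ("[CH2:1]=[CH:2][CH:3]=[CH2:4].[CH2:5]=[CH2:6]"
               ">>[CH2:1]1[CH:2]=[CH:3][CH2:4][CH2:5][CH2:6]1")
ETHENE_HYDROGENATION = "[CH2:1]=[CH2:2].[H:3][H:4]>>[CH3:1][CH3:2]"
ACETYLENE_HYDROGENATION = "[CH:1]#[CH:2].[H:3][H:4]>>[CH2:1]=[CH2:2]"
ALDOL_STEP1 = ("[CH3:1][C:2](=[O:3])[CH2:4][H:8]"
               ">>[CH3:1][C:2]([O:3][H:8])=[CH2:4]")
ALDOL_STEP2 = ("[CH3:1][C:2]([O:3][H:8])=[CH2:4].[CH3:5][CH:6]=[O:7]"
               ">>[CH3:1][C:2](=[O:3])[CH2:4][CH:6]([O:7][H:8])[CH3:5]")

_BENZENE_X = ("[c:1]1([H:21])[c:2]([H:22])[c:3]([H:23])"
              "[c:4]([H:24])[c:5]([H:25])[c:6]1[H:26]")
_NITRO = "[N+:11](=[O:12])[O-:13]"
_HNO3 = f"[O:10]([H:27]){_NITRO}"

NITROPHENOL_REACTIONS: dict[str, str] = {
    # positional selectivity is encoded as full-environment refined rules:
    # the entire substrate ring (explicit hydrogens) is part of the pattern
    "chlorination_benzene":
        f"{_BENZENE_X}.[Cl:7][Cl:8]"
        ">>[c:1]1([Cl:7])[c:2]([H:22])[c:3]([H:23])[c:4]([H:24])[c:5]([H:25])"
        "[c:6]1[H:26].[Cl:8][H:21]",
    "nitration_benzene":
        f"{_BENZENE_X}.{_HNO3}"
        f">>[c:1]1({_NITRO})[c:2]([H:22])[c:3]([H:23])[c:4]([H:24])[c:5]([H:25])"
        "[c:6]1[H:26].[O:10]([H:27])[H:21]",
    "nitration_para_to_cl":
        "[c:1]1([Cl:7])[c:2]([H:22])[c:3]([H:23])[c:4]([H:24])[c:5]([H:25])"
        f"[c:6]1[H:26].{_HNO3}"
        f">>[c:1]1([Cl:7])[c:2]([H:22])[c:3]([H:23])[c:4]({_NITRO})[c:5]([H:25])"
        "[c:6]1[H:26].[O:10]([H:27])[H:24]",
    "chlorination_meta_to_nitro":
        f"[c:1]1({_NITRO})[c:2]([H:22])[c:3]([H:23])[c:4]([H:24])[c:5]([H:25])"
        "[c:6]1[H:26].[Cl:7][Cl:8]"
        f">>[c:1]1({_NITRO})[c:2]([H:22])[c:3]([Cl:7])[c:4]([H:24])[c:5]([H:25])"
        "[c:6]1[H:26].[Cl:8][H:23]",
    "hydrolysis_aryl_chloride":
        "[c:1]1([Cl:7])[c:2]([H:22])[c:3]([H:23])[c:4]([H:24])[c:5]([H:25])"
        "[c:6]1[H:26].[O:14]([H:28])[H:29]"
        ">>[c:1]1([O:14][H:28])[c:2]([H:22])[c:3]([H:23])[c:4]([H:24])[c:5]([H:25])"
        "[c:6]1[H:26].[Cl:7][H:29]",
    "nitration_of_phenol":
        "[c:1]1([O:14][H:28])[c:2]([H:22])[c:3]([H:23])[c:4]([H:24])[c:5]([H:25])"
        f"[c:6]1[H:26].{_HNO3}"
        f">>[c:1]1([O:14][H:28])[c:2]([H:22])[c:3]([H:23])[c:4]({_NITRO})"
        "[c:5]([H:25])[c:6]1[H:26].[O:10]([H:27])[H:24]",
}

#: rules extracted from full-molecule environments, except hydrolysis
#: which is a radius-1 generic aryl-chloride rule
_NITROPHENOL_RADII = {"hydrolysis_aryl_chloride": 1}


def nitrophenol_rules() -> dict[str, RuleSpan]:
    out = {}
    for name, smi in NITROPHENOL_REACTIONS.items():
        radius = _NITROPHENOL_RADII.get(name, 99)
        its = build_its(parse_reaction_smiles(smi), complete_hydrogens=False)
        out[name] = extract_rule(reaction_center(its, radius), rule_id=name)
    return out


def nitrophenol_seeds() -> tuple[list[nx.Graph], list[int]]:
    """Seed species (benzene, Cl2, nitric acid, water) and the indices of the
    abundant reagents."""
    seeds = [parse_smiles(s) for s in
             ("c1ccccc1", "ClCl", "O[N+](=O)[O-]", "O")]
    return seeds, [1, 2, 3]


P_NITROPHENOL_SMILES = "Oc1ccc(cc1)[N+](=O)[O-]"


# ---------------------------------------------------------------------------
# random route-search instances (functional-group interconversion networks)
# ---------------------------------------------------------------------------

#: substituent -> implicit hcount of the free hydride (HX, H2O, NH3, H2S)
_GROUP_H = {"F": 0, "Cl": 0, "Br": 0, "I": 0, "O": 1, "N": 2, "S": 1}


def _group_token(sym: str, extra_h: int, amap: int) -> str:
    h = _GROUP_H[sym] + extra_h
    hs = "" if h == 0 else ("H" if h == 1 else f"H{h}")
    return f"[{sym}{hs}:{amap}]"


def substitution_rule(a: str, b: str) -> RuleSpan:
    """Radius-0 rule converting substituent ``a`` into ``b`` on a carbon,
    with the hydride of ``b`` as co-reagent and the hydride of ``a`` as
    by-product (a formal functional-group interconversion)."""
    smi = (f"[CH3:1]{_group_token(a, 0, 2)}.{_group_token(b, 0, 3)}[H:4]"
           f">>[CH3:1]{_group_token(b, 0, 3)}.{_group_token(a, 0, 2)}[H:4]")
    its = build_its(parse_reaction_smiles(smi), complete_hydrogens=False)
    return extract_rule(reaction_center(its, 0), rule_id=f"sub_{a}_to_{b}")


def route_instance(seed: int) -> dict:
    """A random functional-group interconversion network on a propyl
    scaffold: seeds, directed substitution rules, a start and a goal group.
    The shortest route length equals the BFS distance in the group digraph,
    which serves as an independent optimality oracle."""
    rng = random.Random(seed)
    groups = sorted(rng.sample(sorted(_GROUP_H), 5))
    edges = [(a, b) for a in groups for b in groups
             if a != b and rng.random() < 0.35]
    start, goal = rng.sample(groups, 2)
    mol = parse_smiles(f"CCC{start}" if start not in ("O", "N", "S")
                       else f"CCC{start}")
    hydrides = [parse_smiles({"F": "F", "Cl": "Cl", "Br": "Br", "I": "I",
                              "O": "O", "N": "N", "S": "S"}[g]) for g in groups]
    return {
        "groups": groups,
        "edges": edges,
        "start": start,
        "goal": goal,
        "seeds": [mol] + hydrides,
        "abundant": list(range(1, len(groups) + 1)),
        "rules": [substitution_rule(a, b) for a, b in edges],
        "target": parse_smiles(f"CCC{goal}"),
    }


def worked_examples() -> dict:
    """Named fixture set used throughout the documentation and tests."""
    but2ene_core = parse_smiles("[CH3:1][CH:2]=[CH:3][CH3:4]")
    return {
        "diels_alder": DIELS_ALDER,
        "ethene_hydrogenation": ETHENE_HYDROGENATION,
        "acetylene_hydrogenation": ACETYLENE_HYDROGENATION,
        "aldol_2step": (ALDOL_STEP1, ALDOL_STEP2),
        "but2ene": "CC=CC",
        "but2ene_identity_rule": identity_rule(but2ene_core, "but2ene_id"),
        "nitrophenol_rules": nitrophenol_rules(),
        "nitrophenol_seeds": nitrophenol_seeds(),
        "p_nitrophenol": P_NITROPHENOL_SMILES,
    }
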