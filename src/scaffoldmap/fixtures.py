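"""Synthetic compound libraries with known-by-construction scaffold chains.

The generator assembles molecules from a fixed vocabulary of ring-system
frameworks (aromatic, saturated, fused, bridged, spiro, linked, branched,
disconnected, a steroid nucleus, plus acyclic chains) decorated with random
side chains.  Because side chains never touch the framework, every
molecule's scaffold chain is determined by its template — and for each
template the chain is specified *by hand* in this file, level by level:
SMILES for the chemical levels, explicit edge lists for the contracted
graph levels, and ring-connectivity specs for the top levels.  The
resulting ground-truth table is an exact oracle for the scaffold engine
and for hierarchy statistics.

What this library emulates: a small, structurally diverse screening
library spanning ring counts 0-4 with realistic scaffold sharing (several
molecules per framework, several frameworks per graph framework, and so
on up the hierarchy).  What it does not emulate: the size, tautomer
complexity, charge states and exotic ring systems of a real registry
database — conclusions about branching-factor magnitudes on real data do
not follow from it.
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import networkx as nx
import pandas as pd
from rdkit import Chem

from .chem_io import (EMPTY_KEY, Molecule, ScaffoldChain, ScaffoldKey,
                      canonical_key)

Edge = tuple[int, int]


@dataclass(frozen=True)
class FrameworkTemplate:
    """One vocabulary entry: a framework and its hand-derived scaffolds.

    ``level5_edges`` defaults to the framework skeleton (frameworks
    without superfluous linker atoms are their own level-5 scaffold).
    """

    name: str
    framework: str | None                     # SMILES; None => acyclic
    ring_count: int
    level4_edges: tuple[Edge, ...]
    level3_strong: tuple[Edge, ...] = ()
    level3_weak: tuple[Edge, ...] = ()
    level5_edges: tuple[Edge, ...] | None = None
    level7_smiles: str | None = None          # differs only when stereo present
    framework_edges: tuple[Edge, ...] | None = None  # build instead of parse
    weight: float = 1.0
    acyclic_bodies: tuple[str, ...] = ()


def _hexagon(offset: int) -> list[Edge]:
    return [(offset + i, offset + (i + 1) % 6) for i in range(6)]


#: Gonane (steroid nucleus): 6-6-6-5 edge-fused tetracycle, standard
#: numbering C1..C17 mapped to 0..16.
_GONANE_EDGES: tuple[Edge, ...] = (
    (0, 1), (1, 2), (2, 3), (3, 4), (4, 9), (9, 0),          # ring A
    (4, 5), (5, 6), (6, 7), (7, 8), (8, 9),                  # ring B
    (7, 13), (13, 12), (12, 11), (11, 10), (10, 8),          # ring C
    (12, 16), (16, 15), (15, 14), (14, 13),                  # ring D
)

#: Two edge-fused triangles: the ring topology of every fused bicyclic.
_FUSED_PAIR_L4: tuple[Edge, ...] = ((0, 1), (0, 2), (1, 2), (0, 3), (1, 3))
_TRIANGLE: tuple[Edge, ...] = ((0, 1), (1, 2), (2, 0))
_TWO_TRIANGLES: tuple[Edge, ...] = _TRIANGLE + ((3, 4), (4, 5), (5, 3))

TEMPLATES: tuple[FrameworkTemplate, ...] = (
    FrameworkTemplate(
        name="benzene", framework="c1ccccc1", ring_count=1,
        level4_edges=_TRIANGLE, weight=3.0),
    FrameworkTemplate(
        name="cyclohexane", framework="C1CCCCC1", ring_count=1,
        level4_edges=_TRIANGLE, weight=1.5),
    FrameworkTemplate(
        name="pyridine", framework="c1ccncc1", ring_count=1,
        level4_edges=_TRIANGLE, weight=2.0),
    FrameworkTemplate(
        name="piperidine", framework="C1CCNCC1", ring_count=1,
        level4_edges=_TRIANGLE, weight=1.0),
    FrameworkTemplate(
        name="naphthalene", framework="c1ccc2ccccc2c1", ring_count=2,
        level4_edges=_FUSED_PAIR_L4, level3_strong=((0, 1),), weight=1.5),
    FrameworkTemplate(
        name="decalin", framework="C1CCC2CCCCC2C1", ring_count=2,
        level4_edges=_FUSED_PAIR_L4, level3_strong=((0, 1),)),
    FrameworkTemplate(
        name="cis-decalin", framework="C1CC[C@H]2CCCC[C@@H]2C1",
        level7_smiles="C1CCC2CCCCC2C1", ring_count=2,
        level4_edges=_FUSED_PAIR_L4, level3_strong=((0, 1),), weight=0.5),
    FrameworkTemplate(
        name="indane", framework="C1Cc2ccccc2C1", ring_count=2,
        level4_edges=_FUSED_PAIR_L4, level3_strong=((0, 1),)),
    FrameworkTemplate(
        name="norbornane", framework="C1CC2CCC1C2", ring_count=2,
        level4_edges=_FUSED_PAIR_L4, level3_strong=((0, 1),), weight=0.5),
    FrameworkTemplate(
        name="spiro[4.5]decane", framework="C1CCC2(C1)CCCCC2", ring_count=2,
        level4_edges=((0, 1), (1, 2), (2, 0), (2, 3), (3, 4), (4, 2)),
        level3_weak=((0, 1),), weight=0.5),
    FrameworkTemplate(
        name="biphenyl", framework="c1ccc(-c2ccccc2)cc1", ring_count=2,
        level4_edges=_TWO_TRIANGLES + ((0, 3),),
        level3_weak=((0, 1),), weight=1.5),
    FrameworkTemplate(
        name="diphenylmethane", framework="c1ccc(Cc2ccccc2)cc1", ring_count=2,
        level5_edges=tuple(_hexagon(0) + _hexagon(6) + [(0, 6)]),
        level4_edges=_TWO_TRIANGLES + ((0, 3),), level3_weak=((0, 1),)),
    FrameworkTemplate(
        name="bibenzyl", framework="c1ccc(CCc2ccccc2)cc1", ring_count=2,
        level5_edges=tuple(_hexagon(0) + _hexagon(6) + [(0, 6)]),
        level4_edges=_TWO_TRIANGLES + ((0, 3),), level3_weak=((0, 1),)),
    FrameworkTemplate(
        name="1,3-diphenylpropane", framework="c1ccc(CCCc2ccccc2)cc1",
        ring_count=2,
        level5_edges=tuple(_hexagon(0) + _hexagon(6) + [(0, 6)]),
        level4_edges=_TWO_TRIANGLES + ((0, 3),), level3_weak=((0, 1),),
        weight=0.5),
    FrameworkTemplate(
        name="two-benzenes", framework="c1ccccc1.c1ccccc1", ring_count=2,
        level4_edges=_TWO_TRIANGLES, weight=0.3),
    FrameworkTemplate(
        name="anthracene", framework="c1ccc2cc3ccccc3cc2c1", ring_count=3,
        level4_edges=((0, 1), (0, 2), (1, 2), (3, 4), (3, 5), (4, 5),
                      (0, 3), (1, 4)),
        level3_strong=((0, 1), (1, 2))),
    FrameworkTemplate(
        name="2-phenylnaphthalene", framework="c1ccc(-c2ccc3ccccc3c2)cc1",
        ring_count=3,
        level4_edges=((0, 1), (0, 2), (1, 2), (0, 3), (1, 3),
                      (2, 4), (4, 5), (4, 6), (5, 6)),
        level3_strong=((0, 1),), level3_weak=((1, 2),), weight=0.5),
    FrameworkTemplate(
        name="triphenylmethane", framework="C(c1ccccc1)(c2ccccc2)c3ccccc3",
        ring_count=3,
        level5_edges=tuple(_hexagon(1) + _hexagon(7) + _hexagon(13)
                           + [(0, 1), (0, 7), (0, 13)]),
        level4_edges=((1, 2), (2, 3), (3, 1), (4, 5), (5, 6), (6, 4),
                      (7, 8), (8, 9), (9, 7), (0, 1), (0, 4), (0, 7)),
        level3_weak=((0, 1), (0, 2), (1, 2)), weight=0.5),
    FrameworkTemplate(
        name="gonane", framework=None, framework_edges=_GONANE_EDGES,
        ring_count=4,
        level4_edges=((0, 1), (0, 4), (1, 4), (1, 2), (2, 3), (3, 4),
                      (3, 5), (5, 6), (6, 2), (5, 7), (7, 6)),
        level3_strong=((0, 1), (1, 2), (2, 3)), weight=0.7),
    FrameworkTemplate(
        name="acyclic", framework=None, ring_count=0, level4_edges=(),
        acyclic_bodies=("CCO", "CCCCC", "CC(C)CO", "CCN(CC)CC", "CCOC(C)C"),
        weight=1.0),
)

TEMPLATE_INDEX = {t.name: t for t in TEMPLATES}

#: Side chains (attachment point is the first atom of each fragment).
SIDE_CHAINS: tuple[str, ...] = ("C", "CC", "O", "OC", "N", "Cl", "F",
                                "C(=O)O", "C(C)C", "C#N")


# ---------------------------------------------------------------------------
# ground-truth chains
# ---------------------------------------------------------------------------


def _framework_mol(template: FrameworkTemplate) -> Chem.Mol | None:
    if template.framework is not None:
        return Chem.MolFromSmiles(template.framework)
    if template.framework_edges is not None:
        rw = Chem.RWMol()
        n = 1 + max(max(e) for e in template.framework_edges)
        for _ in range(n):
            rw.AddAtom(Chem.Atom(6))
        for u, v in template.framework_edges:
            rw.AddBond(u, v, Chem.BondType.SINGLE)
        mol = rw.GetMol()
        Chem.SanitizeMol(mol)
        return mol
    return None


def _skeleton(mol: Chem.Mol) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(mol.GetNumAtoms()))
    g.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx())
                     for b in mol.GetBonds())
    return g


def _ring_graph(n_rings: int, strong: tuple[Edge, ...],
                weak: tuple[Edge, ...]) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(n_rings))
    g.add_edges_from(((u, v, {"strength": "strong"}) for u, v in strong))
    g.add_edges_from(((u, v, {"strength": "weak"}) for u, v in weak))
    return g


def template_chain(template: FrameworkTemplate) -> ScaffoldChain:
    """The hand-specified ground-truth chain of a template.

    Only :func:`~scaffoldmap.chem_io.canonical_key` is shared with the
    scaffold engine; none of the level transformations are used here.
    """
    mol = _framework_mol(template)
    if mol is None:  # acyclic: empty scaffold everywhere, ring count 0
        return tuple([ScaffoldKey(1, "0")]
                     + [ScaffoldKey(lv, EMPTY_KEY) for lv in range(2, 9)])
    key8 = canonical_key(mol, 8)
    mol7 = Chem.MolFromSmiles(template.level7_smiles) \
        if template.level7_smiles else mol
    key7 = canonical_key(mol7, 7)
    key6 = canonical_key(_skeleton(mol7), 6)
    level5 = nx.Graph(list(template.level5_edges)) \
        if template.level5_edges else _skeleton(mol7)
    key5 = canonical_key(level5, 5)
    key4 = canonical_key(nx.Graph(list(template.level4_edges)), 4)
    rg3 = _ring_graph(template.ring_count, template.level3_strong,
                      template.level3_weak)
    key3 = canonical_key(rg3, 3)
    rg2 = _ring_graph(template.ring_count, (),
                      template.level3_strong + template.level3_weak)
    key2 = canonical_key(rg2, 2)
    key1 = canonical_key(template.ring_count, 1)
    return (key1, key2, key3, key4, key5, key6, key7, key8)


# ---------------------------------------------------------------------------
# molecule assembly
# ---------------------------------------------------------------------------


def _attach_side_chains(mol: Chem.Mol, chains: list[str],
                        rng: random.Random) -> Chem.Mol:
    for smi in chains:
        frag = Chem.MolFromSmiles(smi)
        sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
        if not sites:
            break
        site = rng.choice(sites)
        combined = Chem.RWMol(Chem.CombineMols(mol, frag))
        atom = combined.GetAtomWithIdx(site)
        if atom.GetNumExplicitHs() > 0:  # bracket atoms carry fixed H counts
            atom.SetNumExplicitHs(atom.GetNumExplicitHs() - 1)
        combined.AddBond(site, mol.GetNumAtoms(), Chem.BondType.SINGLE)
        mol = combined.GetMol()
        Chem.SanitizeMol(mol)
    return mol


def generate_fixture_library(
        n: int, seed: int, *,
        template_names: list[str] | None = None,
        side_chain_vocab: tuple[str, ...] = SIDE_CHAINS,
        min_side_chains: int = 0, max_side_chains: int = 3,
) -> tuple[list[Molecule], pd.DataFrame]:
    """Deterministically generate ``n`` molecules plus their ground truth.

    Returns the molecules and a table with one row per molecule: id,
    template name, SMILES and the eight ground-truth scaffold keys
    (columns ``level1`` .. ``level8``).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = random.Random(seed)
    pool = [TEMPLATE_INDEX[t] for t in template_names] if template_names \
        else list(TEMPLATES)
    weights = [t.weight for t in pool]
    chains = {t.name: template_chain(t) for t in pool}

    molecules: list[Molecule] = []
    rows = []
    for i in range(n):
        template = rng.choices(pool, weights=weights, k=1)[0]
        if template.framework is None and template.framework_edges is None:
            mol = Chem.MolFromSmiles(rng.choice(template.acyclic_bodies))
        else:
            mol = _framework_mol(template)
        k = rng.randint(min_side_chains, max_side_chains)
        if k:
            mol = _attach_side_chains(
                mol, [rng.choice(side_chain_vocab) for _ in range(k)], rng)
        molecule = Molecule(id=f"fix-{i:05d}", mol=mol, name=template.name)
        molecules.append(molecule)
        row = {"id": molecule.id, "template": template.name,
               "smiles": molecule.smiles}
        for key in chains[template.name]:
            row[f"level{key.level}"] = key.key
        rows.append(row)
    return molecules, pd.DataFrame(rows)


def ground_truth_chain(row: pd.Series) -> ScaffoldChain:
    """Rebuild the ScaffoldChain from one ground-truth table row."""
    return tuple(ScaffoldKey(lv, row[f"level{lv}"]) for lv in range(1, 9))
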