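"""The eight-level scaffold hierarchy transformations.

Every molecule is mapped to a chain of exactly eight scaffolds, one per
level, each computable from the level below it alone:

====== ===========================  =========================================
level  name                         transformation from the level below
====== ===========================  =========================================
8      rings with linkers, stereo   delete side chains from the standardized
                                    molecule (Bemis-Murcko framework),
                                    keeping whatever stereo survives
7      rings with linkers           discard all stereo marks
6      graph framework              every atom carbon, every bond single
5      graph framework, contracted  splice out degree-2 *linker* atoms
       linkers
4      ring topology (Oprea)        edge-merge remaining degree-2 vertices
                                    unless that would collapse a triangle
3      ring connectivity, extended  one vertex per CSSR ring; strong edge =
                                    fused (shared graph edge), weak edge =
                                    shared vertex or linker-edge path
2      ring connectivity            strong/weak distinction dropped
1      ring count                   number of CSSR rings
====== ===========================  =========================================

Levels 8-7 are represented as RDKit molecules, levels 6-4 as plain
``networkx`` graphs, levels 3-2 as ring-connectivity graphs (``strength``
edge attribute) and level 1 as an integer.  Acyclic molecules collapse to
the empty scaffold at levels 8-2 and ring count 0.
"""

from __future__ import annotations

from typing import Sequence

import networkx as nx
from rdkit import Chem

from .chem_io import (Molecule, ScaffoldChain, ScaffoldKey, canonical_key,
                      parse_key, standardize)

__all__ = [
    "level8", "level7", "level6", "level5", "level4", "level3", "level2",
    "level1", "cssr_rings", "scaffold_chain", "chain_from_key", "RingSet",
]

#: CSSR decomposition: each ring is a frozenset of vertices plus its edges.
RingSet = list[tuple[frozenset, frozenset]]


# ---------------------------------------------------------------------------
# levels 8-6: molecule-space transformations
# ---------------------------------------------------------------------------


def level8(molecule: Molecule) -> Chem.Mol:
    """Molecular framework: iteratively delete terminal heavy atoms.

    Works on the kekulized structure so that removing an exocyclic atom
    that participated in an aromatic system (e.g. a pyridinone carbonyl)
    cannot leave an un-kekulizable aromatic flag behind; aromaticity is
    re-perceived afterwards.  Stereocenters whose defining substituent was
    removed are cleaned up rather than left dangling.  Acyclic molecules
    yield the empty molecule.
    """
    mol = Chem.Mol(standardize(molecule).mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        atom.SetIntProp("_origDegree", atom.GetDegree())
    while True:
        terminal = [a.GetIdx() for a in rw.GetAtoms() if a.GetDegree() <= 1]
        if not terminal:
            break
        for idx in sorted(terminal, reverse=True):
            rw.RemoveAtom(idx)
    out = rw.GetMol()
    if out.GetNumAtoms():
        # atoms that lost a substituent get ordinary implicit-H accounting
        # back (bracket atoms parsed from SMILES carry fixed H counts)
        for atom in out.GetAtoms():
            if atom.GetDegree() < atom.GetIntProp("_origDegree"):
                atom.SetNoImplicit(False)
                atom.SetNumExplicitHs(0)
            atom.ClearProp("_origDegree")
        Chem.SanitizeMol(out)
        Chem.AssignStereochemistry(out, cleanIt=True, force=True)
    return out


def level7(framework: Chem.Mol) -> Chem.Mol:
    """Same graph with every atom/bond stereo mark cleared."""
    mol = Chem.Mol(framework)
    Chem.RemoveStereochemistry(mol)
    return mol


def level6(framework: Chem.Mol) -> nx.Graph:
    """Graph framework: connectivity only, all-carbon, all-single.

    Vertex count still equals the heavy-atom count of the framework.
    """
    graph = nx.Graph()
    graph.add_nodes_from(range(framework.GetNumAtoms()))
    graph.add_edges_from((b.GetBeginAtomIdx(), b.GetEndAtomIdx())
                         for b in framework.GetBonds())
    return graph


# ---------------------------------------------------------------------------
# levels 5-4: graph contractions
# ---------------------------------------------------------------------------


def _ring_vertices(graph: nx.Graph) -> set:
    """Vertices lying on at least one cycle (incident to a non-bridge edge)."""
    bridges = set(map(frozenset, nx.bridges(graph)))
    on_ring = set()
    for u, v in graph.edges():
        if frozenset((u, v)) not in bridges:
            on_ring.update((u, v))
    return on_ring


def level5(graph: nx.Graph) -> nx.Graph:
    """Contract linker paths: splice out every degree-2 non-ring vertex.

    Branching linker vertices (degree >= 3) are kept; ring vertices are
    untouched.  Two anchors can never be joined by more than one linker
    path (parallel paths would be ring edges), which is asserted rather
    than assumed.
    """
    g = graph.copy()
    ring = _ring_vertices(g)
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes()):
            if v in ring or g.degree(v) != 2:
                continue
            a, b = g.neighbors(v)
            # a parallel a-b connection would make v a ring vertex
            assert not g.has_edge(a, b), "linker vertex on a cycle"
            g.remove_node(v)
            g.add_edge(a, b)
            changed = True
    return g


def level4(graph: nx.Graph) -> nx.Graph:
    """Oprea ring topology: edge-merge degree-2 vertices to a fixed point.

    A degree-2 vertex is spliced out (its two edges merged into one)
    unless its neighbors are already adjacent — the triangle exception,
    without which every cycle would vanish.  The result is the minimum
    cycle topological representation: every surviving degree-2 vertex
    lies in a triangle.
    """
    g = graph.copy()
    changed = True
    while changed:
        changed = False
        for v in list(g.nodes()):
            if g.degree(v) != 2:
                continue
            a, b = g.neighbors(v)
            if g.has_edge(a, b):
                continue
            g.remove_node(v)
            g.add_edge(a, b)
            changed = True
    return g


# ---------------------------------------------------------------------------
# ring perception (CSSR) and levels 3-1
# ---------------------------------------------------------------------------


def _cycle_edge_vector(cycle: Sequence, edge_bit: dict) -> int:
    bits = 0
    n = len(cycle)
    for i in range(n):
        bits |= 1 << edge_bit[frozenset((cycle[i], cycle[(i + 1) % n]))]
    return bits


def cssr_rings(graph: nx.Graph) -> RingSet:
    """Complete set of smallest rings (relevant cycles).

    A cycle belongs to the CSSR iff it cannot be written as a symmetric
    difference of strictly shorter cycles — equivalently, iff it is a
    member of *some* minimum cycle basis.  Unlike SSSR this is symmetry
    complete: the cube graph yields all six 4-rings, not an arbitrary
    five.  The size of the set is always >= the cyclomatic number.

    Implementation: every relevant cycle is no longer than the longest
    cycle of one minimum cycle basis, so simple cycles are enumerated up
    to that bound and filtered by GF(2) independence from shorter ones.
    """
    if graph.number_of_edges() == 0:
        return []
    basis = nx.minimum_cycle_basis(graph)
    if not basis:
        return []
    bound = max(len(c) for c in basis)
    edge_bit = {frozenset(e): i for i, e in enumerate(graph.edges())}
    by_len: dict[int, list] = {}
    for cycle in nx.simple_cycles(graph, length_bound=bound):
        by_len.setdefault(len(cycle), []).append(cycle)

    rings: RingSet = []
    span: list[int] = []  # row-reduced GF(2) span of strictly shorter cycles

    def reduce(vec: int) -> int:
        for row in span:
            vec = min(vec, vec ^ row)
        return vec

    for length in sorted(by_len):
        vectors = []
        for cycle in by_len[length]:
            vec = _cycle_edge_vector(cycle, edge_bit)
            vectors.append(vec)
            if reduce(vec) != 0:
                edges = frozenset(
                    frozenset((cycle[i], cycle[(i + 1) % length]))
                    for i in range(length))
                rings.append((frozenset(cycle), edges))
        for vec in vectors:  # shorter-only span: extend after the length pass
            vec = reduce(vec)
            if vec:
                span.append(vec)
                span.sort(reverse=True)
    assert len(rings) >= (graph.number_of_edges() - graph.number_of_nodes()
                          + nx.number_connected_components(graph))
    return rings


def level3(graph: nx.Graph, rings: RingSet | None = None) -> nx.Graph:
    """Extended ring connectivity: one vertex per CSSR ring.

    Edge strength encodes rigidity: *strong* iff the two rings share a
    graph edge (fused), *weak* iff they share only a vertex (spiro) or are
    joined through a path of linker edges.  The path search runs in the
    subgraph of linker (non-ring, i.e. bridge) edges only; ring edges are
    excluded so that e.g. the two terminal rings of anthracene do not pick
    up a spurious edge.  When a pair qualifies as both, strong wins.
    """
    rings = cssr_rings(graph) if rings is None else rings
    rg = nx.Graph()
    rg.add_nodes_from(range(len(rings)))
    # strong / spiro-weak from pairwise overlap
    for i in range(len(rings)):
        vi, ei = rings[i]
        for j in range(i + 1, len(rings)):
            vj, ej = rings[j]
            if ei & ej:
                rg.add_edge(i, j, strength="strong")
            elif vi & vj:
                rg.add_edge(i, j, strength="weak")
    # linker-path weak edges: connectivity in the bridge-edge subgraph
    bridges = [e for e in map(tuple, nx.bridges(graph))]
    if bridges:
        linker = nx.Graph(bridges)
        for comp in nx.connected_components(linker):
            touching = [i for i, (vi, _) in enumerate(rings) if vi & comp]
            for a in range(len(touching)):
                for b in range(a + 1, len(touching)):
                    i, j = touching[a], touching[b]
                    if not rg.has_edge(i, j):
                        rg.add_edge(i, j, strength="weak")
    return rg


def level2(ring_graph: nx.Graph) -> nx.Graph:
    """Plain ring connectivity: every edge strength collapsed to weak."""
    g = ring_graph.copy()
    for _, _, data in g.edges(data=True):
        data["strength"] = "weak"
    return g


def level1(ring_graph: nx.Graph) -> int:
    """Ring count: the number of vertices of the ring-connectivity graph."""
    return ring_graph.number_of_nodes()


# ---------------------------------------------------------------------------
# chains
# ---------------------------------------------------------------------------


def scaffold_chain(molecule: Molecule) -> ScaffoldChain:
    """The full chain of eight scaffold keys (levels 1..8) for a molecule."""
    s8 = level8(molecule)
    s7 = level7(s8)
    s6 = level6(s7)
    s5 = level5(s6)
    s4 = level4(s5)
    rings = cssr_rings(s4)
    s3 = level3(s4, rings)
    s2 = level2(s3)
    s1 = level1(s2)
    return (
        canonical_key(s1, 1),
        canonical_key(s2, 2),
        canonical_key(s3, 3),
        canonical_key(s4, 4),
        canonical_key(s5, 5),
        canonical_key(s6, 6),
        canonical_key(s7, 7),
        canonical_key(s8, 8),
    )


def _step(level: int, scaffold):
    """Transform a parsed level-``level`` scaffold one level up (towards 1)."""
    if level == 8:
        return level7(scaffold)
    if level == 7:
        return level6(scaffold)
    if level == 6:
        return level5(scaffold)
    if level == 5:
        return level4(scaffold)
    if level == 4:
        return level3(scaffold)
    if level == 3:
        return level2(scaffold)
    if level == 2:
        return level1(scaffold)
    raise ValueError(f"no transformation up from level {level}")


def chain_from_key(key: ScaffoldKey) -> list[ScaffoldKey]:
    """Recompute all higher-level keys from one scaffold key alone.

    The hierarchy is molecule-independent above any given level: parsing a
    level-k key and applying the level transformations reproduces the keys
    at levels k-1 .. 1.  Returns keys for levels ``key.level - 1`` down
    to 1, in descending level order.
    """
    scaffold = parse_key(key)
    out: list[ScaffoldKey] = []
    for lv in range(key.level, 1, -1):
        scaffold = _step(lv, scaffold)
        out.append(canonical_key(scaffold, lv - 1))
    return out
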