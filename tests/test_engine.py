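"""Level transformations, CSSR ring perception and scaffold chains."""

import itertools
import random

import networkx as nx
import pytest
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from scaffoldmap import (EMPTY_KEY, canonical_key, cssr_rings, level2, level3,
                         level4, level5, level6, level7, level8,
                         scaffold_chain)
from scaffoldmap.engine import chain_from_key
from scaffoldmap.fixtures import ground_truth_chain

from conftest import DRUGS, mol_from_smiles


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def contract_oracle(graph: nx.Graph, protect_rings: bool, rng: random.Random
                    ) -> nx.Graph:
    """Brute-force degree-2 contraction in random vertex order.

    Re-derives ring membership from scratch at every step (a vertex is on a
    ring iff removing it and joining its neighbors changes no cycle), so it
    shares no code with the implementation under test.
    """
    g = graph.copy()
    while True:
        candidates = []
        for v in g.nodes():
            if g.degree(v) != 2:
                continue
            a, b = g.neighbors(v)
            if g.has_edge(a, b):
                continue  # triangle (level 4) / ring vertex (level 5)
            if protect_rings and any(v in cyc for cyc in nx.cycle_basis(g)):
                continue
            candidates.append(v)
        if not candidates:
            return g
        v = rng.choice(candidates)
        a, b = g.neighbors(v)
        g.remove_node(v)
        g.add_edge(a, b)


def all_small_cycles(graph: nx.Graph, bound: int = 12) -> list[frozenset]:
    """Exhaustive simple-cycle enumeration by DFS from every edge."""
    cycles = set()
    for start in graph.nodes():
        stack = [(start, [start])]
        while stack:
            node, path = stack.pop()
            for nxt in graph.neighbors(node):
                if nxt == start and len(path) >= 3:
                    cycles.add(frozenset(path))
                elif nxt not in path and len(path) < bound:
                    stack.append((nxt, path + [nxt]))
    return sorted(cycles, key=len)


def random_framework(rng: random.Random, n_max: int = 20) -> nx.Graph:
    """Random connected graph with terminal vertices pruned away."""
    while True:
        n = rng.randint(4, n_max)
        p = rng.uniform(1.8 / n, 3.5 / n)
        g = nx.gnp_random_graph(n, p, seed=rng.randint(0, 2**31 - 1))
        if g.number_of_edges() == 0:
            continue
        g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
        while True:
            leaves = [v for v in g.nodes() if g.degree(v) <= 1]
            if not leaves:
                break
            g.remove_nodes_from(leaves)
        if g.number_of_nodes() >= 3:
            return g


# ---------------------------------------------------------------------------
# level 8: molecular framework
# ---------------------------------------------------------------------------


class TestLevel8:
    def test_toluene_gives_benzene(self):
        out = level8(mol_from_smiles("Cc1ccccc1"))
        assert Chem.MolToSmiles(out) == "c1ccccc1"

    def test_acyclic_gives_empty_graph(self):
        assert level8(mol_from_smiles("CCO")).GetNumAtoms() == 0

    @pytest.mark.parametrize("name", sorted(DRUGS))
    def test_matches_independent_murcko_routine(self, name):
        # oracle: RDKit's own Murcko framework on the standardized molecule.
        # RDKit retains exocyclic multiply-bonded atoms (e.g. lactam =O);
        # in this hierarchy those are side-chain atoms (non-ring,
        # non-linker), so the oracle prunes them afterwards.
        from scaffoldmap import standardize
        std = standardize(mol_from_smiles(DRUGS[name]))
        core = Chem.RWMol(MurckoScaffold.GetScaffoldForMol(std.mol))
        while True:
            terminal = [a.GetIdx() for a in core.GetAtoms()
                        if a.GetDegree() <= 1]
            if not terminal:
                break
            for idx in sorted(terminal, reverse=True):
                core.RemoveAtom(idx)
        expected = core.GetMol()
        for atom in expected.GetAtoms():
            atom.SetNoImplicit(False)
            atom.SetNumExplicitHs(0)
        Chem.SanitizeMol(expected)
        # the oracle discards chirality on every atom it edits, even when
        # the center stays stereogenic; compare the stereo-free framework
        # (stereo retention has its own test)
        Chem.RemoveStereochemistry(expected)
        got = level7(level8(std))
        assert Chem.MolToSmiles(Chem.Mol(got)) == Chem.MolToSmiles(expected)

    def test_disconnection_preserved(self):
        out = level8(mol_from_smiles("Cc1ccccc1.c1ccccc1C"))
        assert Chem.MolToSmiles(out) == "c1ccccc1.c1ccccc1"

    def test_stereo_kept_only_while_defined(self):
        # ring-fusion stereo survives side-chain removal
        out = level8(mol_from_smiles("CC1CC[C@H]2CCCC[C@@H]2C1"))
        assert "@" in Chem.MolToSmiles(out)
        # a stereocenter defined by its side chain loses its mark
        out = level8(mol_from_smiles("C[C@H](O)C1CCCCC1"))
        assert "@" not in Chem.MolToSmiles(out)


class TestLevel7:
    def test_stereo_marks_cleared_counts_unchanged(self):
        s8 = level8(mol_from_smiles("CC1CC[C@H]2CCCC[C@@H]2C1"))
        s7 = level7(s8)
        assert s7.GetNumAtoms() == s8.GetNumAtoms()
        assert s7.GetNumBonds() == s8.GetNumBonds()
        assert "@" not in Chem.MolToSmiles(s7)

    def test_identity_on_stereo_free_input(self):
        s8 = level8(mol_from_smiles("c1ccccc1"))
        assert Chem.MolToSmiles(level7(s8)) == "c1ccccc1"

    def test_heteroatoms_kept(self):
        s7 = level7(level8(mol_from_smiles(DRUGS["sulfamethoxazole"])))
        symbols = {a.GetSymbol() for a in s7.GetAtoms()}
        assert {"S", "N", "O"} <= symbols


class TestLevel6:
    def test_pyridine_equals_benzene_graph_framework(self):
        g_pyr = level6(level7(level8(mol_from_smiles("c1ccncc1"))))
        g_ben = level6(level7(level8(mol_from_smiles("c1ccccc1"))))
        assert canonical_key(g_pyr, 6) == canonical_key(g_ben, 6)

    def test_vertex_count_equals_framework_heavy_atoms(self):
        s8 = level8(mol_from_smiles(DRUGS["diazepam"]))
        assert level6(level7(s8)).number_of_nodes() == s8.GetNumAtoms()

    def test_sulfamethoxazole_framework_two_rings_with_linker(self):
        # expected graph hand-built: 6-ring and 5-ring joined by a 2-atom path
        expected = nx.Graph()
        expected.add_edges_from([(i, (i + 1) % 6) for i in range(6)])
        expected.add_edges_from([(6 + i, 6 + (i + 1) % 5) for i in range(5)])
        expected.add_edges_from([(0, 11), (11, 12), (12, 6)])
        g = level6(level7(level8(mol_from_smiles(DRUGS["sulfamethoxazole"]))))
        assert nx.is_isomorphic(g, expected)


# ---------------------------------------------------------------------------
# levels 5-4: contractions
# ---------------------------------------------------------------------------


def graph_from_smiles_skeleton(smiles: str) -> nx.Graph:
    return level6(level7(level8(mol_from_smiles(smiles))))


class TestLevel5:
    def test_diphenylmethane_contracts_to_biphenyl_graph(self):
        got = level5(graph_from_smiles_skeleton("c1ccc(Cc2ccccc2)cc1"))
        biphenyl = graph_from_smiles_skeleton("c1ccc(-c2ccccc2)cc1")
        assert canonical_key(got, 5) == canonical_key(biphenyl, 5)

    def test_biphenyl_is_fixed_point(self):
        g = graph_from_smiles_skeleton("c1ccc(-c2ccccc2)cc1")
        assert canonical_key(level5(g), 5) == canonical_key(g, 5)

    def test_branching_linker_vertex_survives(self):
        got = level5(graph_from_smiles_skeleton("C(c1ccccc1)(c2ccccc2)c3ccccc3"))
        assert got.number_of_nodes() == 19  # 3 hexagons + 1 hub
        degrees = sorted(d for _, d in got.degree())
        assert degrees.count(3) == 4  # hub + three attachment carbons

    def test_ring_vertices_untouched(self):
        g = graph_from_smiles_skeleton("c1ccccc1")
        assert nx.utils.graphs_equal(level5(g), g)


class TestLevel4:
    @pytest.mark.parametrize("n", [3, 4, 6, 9])
    def test_isolated_cycle_contracts_to_triangle(self, n):
        got = level4(nx.cycle_graph(n))
        assert got.number_of_nodes() == 3 and got.number_of_edges() == 3

    def test_naphthalene_two_triangles_sharing_an_edge(self):
        got = level4(level5(graph_from_smiles_skeleton("c1ccc2ccccc2c1")))
        expected = nx.Graph([(0, 1), (0, 2), (1, 2), (0, 3), (1, 3)])
        assert nx.is_isomorphic(got, expected)

    def test_spiro_two_triangles_sharing_a_vertex(self):
        got = level4(level5(graph_from_smiles_skeleton("C1CCC2(C1)CCCCC2")))
        expected = nx.Graph([(0, 1), (1, 2), (2, 0), (2, 3), (3, 4), (4, 2)])
        assert nx.is_isomorphic(got, expected)

    def test_matches_contraction_oracle_on_random_graphs(self):
        rng = random.Random(42)
        for trial in range(500):
            g = random_framework(rng)
            got5 = level5(g)
            oracle5 = contract_oracle(g, protect_rings=True,
                                      rng=random.Random(trial))
            assert canonical_key(got5, 5) == canonical_key(oracle5, 5)
            got4 = level4(got5)
            oracle4 = contract_oracle(got5, protect_rings=False,
                                      rng=random.Random(trial + 1))
            assert canonical_key(got4, 4) == canonical_key(oracle4, 4)

    def test_oprea_minimality(self):
        # no level-4 vertex of degree 2 with non-adjacent neighbors
        rng = random.Random(7)
        graphs = [random_framework(rng) for _ in range(100)]
        for g in graphs:
            out = level4(level5(g))
            for v in out.nodes():
                if out.degree(v) == 2:
                    a, b = out.neighbors(v)
                    assert out.has_edge(a, b)


# ---------------------------------------------------------------------------
# CSSR
# ---------------------------------------------------------------------------


class TestCssr:
    def test_benzene_one_ring(self):
        assert len(cssr_rings(nx.cycle_graph(6))) == 1

    def test_cube_graph_six_rings_where_sssr_gives_five(self):
        cube = nx.convert_node_labels_to_integers(nx.hypercube_graph(3))
        rings = cssr_rings(cube)
        assert len(rings) == 6
        assert all(len(vs) == 4 for vs, _ in rings)

    def test_naphthalene_two_six_rings(self):
        g = graph_from_smiles_skeleton("c1ccc2ccccc2c1")
        rings = cssr_rings(g)
        assert sorted(len(vs) for vs, _ in rings) == [6, 6]

    def test_bridged_bicyclic_excludes_envelope_ring(self):
        g = graph_from_smiles_skeleton("C1CC2CCC1C2")  # norbornane
        assert sorted(len(vs) for vs, _ in cssr_rings(g)) == [5, 5]

    def test_agrees_with_rdkit_symmetrized_sssr_on_fixtures(self, fixture_library):
        mols, _ = fixture_library
        for m in mols[:100]:
            s7 = level7(level8(m))
            if s7.GetNumAtoms() == 0:
                continue
            assert len(cssr_rings(level6(s7))) == len(Chem.GetSymmSSSR(s7))

    def test_every_ring_is_a_cycle_and_count_bounds(self):
        rng = random.Random(3)
        for _ in range(100):
            g = random_framework(rng)
            rings = cssr_rings(g)
            cyclomatic = (g.number_of_edges() - g.number_of_nodes()
                          + nx.number_connected_components(g))
            assert len(rings) >= cyclomatic
            small = all_small_cycles(g, bound=max(len(v) for v, _ in rings))
            for vs, es in rings:
                assert vs in small
                for e in es:
                    assert g.has_edge(*tuple(e))


# ---------------------------------------------------------------------------
# levels 3-1
# ---------------------------------------------------------------------------


class TestLevel3:
    def test_anthracene_linear_path_no_terminal_edge(self):
        g4 = level4(level5(graph_from_smiles_skeleton("c1ccc2cc3ccccc3cc2c1")))
        rg = level3(g4)
        assert rg.number_of_nodes() == 3
        strengths = sorted(d["strength"] for _, _, d in rg.edges(data=True))
        assert strengths == ["strong", "strong"]
        degrees = sorted(d for _, d in rg.degree())
        assert degrees == [1, 1, 2]  # a path, not a triangle

    def test_fused_vs_linked_vs_spiro_distinguished(self):
        keys = set()
        for smi in ("c1ccc2ccccc2c1", "c1ccc(-c2ccccc2)cc1",
                    "C1CCC2(C1)CCCCC2"):
            g4 = level4(level5(graph_from_smiles_skeleton(smi)))
            keys.add(canonical_key(level3(g4), 3))
        assert keys == {  # strong pair / weak pair / weak pair
            canonical_key_pair("strong"), canonical_key_pair("weak")}

    def test_disconnected_rings_have_no_edge(self):
        g4 = level4(level5(graph_from_smiles_skeleton("c1ccccc1.c1ccccc1")))
        rg = level3(g4)
        assert rg.number_of_nodes() == 2 and rg.number_of_edges() == 0

    def test_strong_iff_shared_edge_oracle(self):
        rng = random.Random(9)
        checked = 0
        while checked < 100:
            g = random_framework(rng)
            rings = cssr_rings(g)
            if len(rings) > 8:
                continue
            rg = level3(g, rings)
            for i, j in itertools.combinations(range(len(rings)), 2):
                shares_edge = bool(rings[i][1] & rings[j][1])
                is_strong = (rg.has_edge(i, j)
                             and rg.edges[i, j]["strength"] == "strong")
                assert shares_edge == is_strong
            checked += 1


def canonical_key_pair(strength: str):
    g = nx.Graph()
    g.add_edge(0, 1, strength=strength)
    return canonical_key(g, 3)


class TestLevel2And1:
    def test_fused_and_linked_collapse_to_same_level2(self):
        keys = set()
        for smi in ("c1ccc2ccccc2c1", "c1ccc(-c2ccccc2)cc1"):
            g4 = level4(level5(graph_from_smiles_skeleton(smi)))
            keys.add(canonical_key(level2(level3(g4)), 2))
        assert len(keys) == 1

    def test_disconnected_pair_distinct_from_connected_pair(self):
        g_conn = level3(level4(level5(
            graph_from_smiles_skeleton("c1ccc(-c2ccccc2)cc1"))))
        g_disc = level3(level4(level5(
            graph_from_smiles_skeleton("c1ccccc1.c1ccccc1"))))
        assert canonical_key(level2(g_conn), 2) != \
            canonical_key(level2(g_disc), 2)

    @pytest.mark.parametrize("smiles, expected", [
        ("c1ccccc1", 1), ("CC", 0), (DRUGS["hydrocortisone"], 4),
        (DRUGS["ibuprofen"], 1), (DRUGS["diazepam"], 3),
    ])
    def test_ring_count(self, smiles, expected):
        chain = scaffold_chain(mol_from_smiles(smiles))
        assert chain[0].key == str(expected)

    def test_ring_count_equals_brute_force_cssr_of_framework(self):
        for smi in DRUGS.values():
            g = graph_from_smiles_skeleton(smi)
            chain = scaffold_chain(mol_from_smiles(smi))
            assert int(chain[0].key) == len(cssr_rings(g))


# ---------------------------------------------------------------------------
# chains and hierarchy-wide properties
# ---------------------------------------------------------------------------


class TestScaffoldChain:
    def test_exactly_eight_keys_levels_ascending(self):
        for smi in DRUGS.values():
            chain = scaffold_chain(mol_from_smiles(smi))
            assert [k.level for k in chain] == list(range(1, 9))

    def test_acyclic_molecule_sentinels(self):
        chain = scaffold_chain(mol_from_smiles("CCO"))
        assert chain[0].key == "0"
        assert all(k.key == EMPTY_KEY for k in chain[1:])

    def test_matches_ground_truth_on_fixture_library(self, fixture_library):
        mols, truth = fixture_library
        for mol, (_, row) in zip(mols, truth.iterrows()):
            assert scaffold_chain(mol) == ground_truth_chain(row)

    def test_idempotence_of_level_transforms(self, fixture_library):
        mols, _ = fixture_library
        for m in mols[:40]:
            s7 = level7(level8(m))
            assert Chem.MolToSmiles(level7(s7)) == Chem.MolToSmiles(s7)
            s5 = level5(level6(s7))
            assert canonical_key(level5(s5), 5) == canonical_key(s5, 5)
            s4 = level4(s5)
            assert canonical_key(level4(s4), 4) == canonical_key(s4, 4)

    def test_cycle_count_conserved_across_contractions(self, fixture_library):
        mols, _ = fixture_library
        for m in mols:
            s6 = level6(level7(level8(m)))
            s5 = level5(s6)
            s4 = level4(s5)
            counts = {len(cssr_rings(g)) for g in (s6, s5, s4)}
            assert len(counts) == 1

    def test_functoriality_higher_levels_molecule_independent(
            self, fixture_library):
        mols, _ = fixture_library
        for m in mols[:150]:
            chain = scaffold_chain(m)
            for key in chain[1:]:
                expected = [chain[lv - 1] for lv in range(key.level - 1, 0, -1)]
                assert chain_from_key(key) == expected
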