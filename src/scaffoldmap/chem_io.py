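"""Molecule input/output, standardization and canonical scaffold keys.

This module is the boundary between chemical file formats (SMILES, SDF,
optionally gzip-compressed) and the in-memory objects the scaffold engine
works on.  It also owns the canonical string encoding of scaffold graphs:
every node of the scaffold hierarchy is identified by a ``(level, key)``
pair where the key is a canonical linear notation, invariant under any
reordering of the input atoms and bonds.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Literal, NamedTuple

import networkx as nx
from rdkit import Chem, RDLogger
from rdkit.Chem.MolStandardize import rdMolStandardize

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

#: Key of the virtual root node (level 0).
ROOT_KEY = "ROOT"
#: Key shared by all acyclic molecules at levels 2-8 (the empty scaffold).
EMPTY_KEY = "-"

Format = Literal["smiles", "sdf", "auto"]


@dataclass
class Molecule:
    """A parsed chemical structure plus identity metadata.

    Disconnected structures are kept whole; the largest-fragment reduction
    common elsewhere is deliberately *not* applied, because multi-fragment
    compounds occupy their own ring-connectivity scaffolds (two disconnected
    rings are a different topology than two connected ones).
    """

    id: str
    mol: Chem.Mol
    name: str | None = None
    comment: str | None = None

    @property
    def smiles(self) -> str:
        return Chem.MolToSmiles(self.mol)


class ScaffoldKey(NamedTuple):
    """Identity of one scaffold node: hierarchy level and canonical string."""

    level: int
    key: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"L{self.level}:{self.key}"


#: A molecule's scaffold chain: exactly eight keys, levels 1..8.
ScaffoldChain = tuple[ScaffoldKey, ...]


class ReadResult(NamedTuple):
    molecules: list["Molecule"]
    skipped: int


# ---------------------------------------------------------------------------
# reading / writing
# ---------------------------------------------------------------------------


def _open_text(path: Path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _detect_format(path: Path) -> str:
    name = path.name.lower()
    if name.endswith(".gz"):
        name = name[:-3]
    if name.endswith((".sdf", ".sd", ".mol")):
        return "sdf"
    if name.endswith((".smi", ".smiles", ".csmiles", ".txt")):
        return "smiles"
    # content sniff: molfile blocks contain the V2000 counts-line tag
    with _open_text(path) as fh:
        head = fh.read(4096)
    return "sdf" if "V2000" in head or "$$$$" in head else "smiles"


def _iter_smiles(fh: IO[str]) -> Iterator[tuple[Chem.Mol | None, str, str | None]]:
    for line in fh:
        line = line.strip()
        if not line:
            continue
        parts = line.split(None, 1)
        smi = parts[0]
        name = parts[1].strip() if len(parts) > 1 else None
        yield Chem.MolFromSmiles(smi), smi, name


def _iter_sdf(fh: IO[str]) -> Iterator[tuple[Chem.Mol | None, str, str | None]]:
    block: list[str] = []
    for line in fh:
        if line.startswith("$$$$"):
            text = "".join(block)
            block = []
            if text.strip():
                mol = Chem.MolFromMolBlock(text, sanitize=True)
                name = text.splitlines()[0].strip() or None if text else None
                yield mol, text, name
        else:
            block.append(line)
    if "".join(block).strip():
        text = "".join(block)
        mol = Chem.MolFromMolBlock(text, sanitize=True)
        yield mol, text, text.splitlines()[0].strip() or None


def read_molecules(path: str | Path, format: Format = "auto") -> ReadResult:
    """Read a SMILES or SDF file (plain or gzipped).

    Unparseable records never abort the stream: they are logged, skipped
    and counted, which is the only workable contract for batch processing
    of large heterogeneous libraries.

    Returns
    -------
    ReadResult
        ``molecules`` in file order and the number of skipped records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path) if format == "auto" else format
    reader = _iter_smiles if fmt == "smiles" else _iter_sdf
    molecules: list[Molecule] = []
    skipped = 0
    with _open_text(path) as fh:
        for i, (mol, raw, name) in enumerate(reader(fh)):
            if mol is None:
                skipped += 1
                log.warning("record %d unparseable, skipped: %.60s", i, raw)
                continue
            mid = name if (fmt == "sdf" and name) else str(i)
            molecules.append(Molecule(id=mid, mol=mol, name=name, comment=None))
    return ReadResult(molecules, skipped)


def write_molecules(molecules: Iterable[Molecule], path: str | Path,
                    format: Format = "auto") -> int:
    """Write molecules as SMILES (``.smi``) or SDF; ``.gz`` compresses."""
    path = Path(path)
    fmt = format
    if fmt == "auto":
        name = path.name[:-3] if path.name.endswith(".gz") else path.name
        fmt = "sdf" if name.endswith((".sdf", ".sd")) else "smiles"
    opener = gzip.open if path.name.endswith(".gz") else open
    n = 0
    with opener(path, "wt") as fh:  # type: ignore[operator]
        if fmt == "smiles":
            for m in molecules:
                fh.write(m.smiles + (f" {m.name}" if m.name else "") + "\n")
                n += 1
        else:
            for m in molecules:
                block = Chem.MolToMolBlock(m.mol)
                if m.name:
                    block = m.name + block[block.index("\n"):]
                fh.write(block)
                fh.write("$$$$\n")
                n += 1
    return n


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

_uncharger = rdMolStandardize.Uncharger()


def standardize(molecule: Molecule) -> Molecule:
    """Normalize a molecule for scaffold extraction.

    Applies aromatic perception, neutralizes formal charges where a proton
    can be added or removed without breaking standard valence (zwitterions
    and fixed charges such as quaternary ammonium keep their charge),
    removes explicit hydrogens and radical flags, and clears isotope
    labels.  Idempotent; disconnected structures stay whole.
    """
    mol = Chem.Mol(molecule.mol)
    mol = _uncharger.uncharge(mol)
    mol = Chem.RemoveHs(mol)
    changed = False
    for atom in mol.GetAtoms():
        if atom.GetIsotope():
            atom.SetIsotope(0)
            changed = True
        if atom.GetNumRadicalElectrons():
            atom.SetNumRadicalElectrons(0)
            atom.SetNoImplicit(False)  # let hydrogens fill the freed valence
            changed = True
    if changed:
        Chem.SanitizeMol(mol)
    if any(a.GetFormalCharge() for a in mol.GetAtoms()):
        log.debug("molecule %s keeps non-neutralizable charge", molecule.id)
    return Molecule(id=molecule.id, mol=mol, name=molecule.name,
                    comment=molecule.comment)


# ---------------------------------------------------------------------------
# canonical keys
# ---------------------------------------------------------------------------


def _graph_to_rwmol(graph: nx.Graph, element: int) -> Chem.Mol:
    """Encode an abstract scaffold graph as an unsanitized RDKit mol.

    Vertices of the contracted graphs can exceed any real element valence,
    so implicit-H bookkeeping and valence checks are disabled; ring
    perception is the only property the SMILES writer needs.
    """
    rw = Chem.RWMol()
    index = {}
    for v in sorted(graph.nodes(), key=repr):
        a = Chem.Atom(element)
        a.SetNoImplicit(True)
        index[v] = rw.AddAtom(a)
    for u, v, data in graph.edges(data=True):
        order = Chem.BondType.DOUBLE if data.get("strength") == "strong" \
            else Chem.BondType.SINGLE
        rw.AddBond(index[u], index[v], order)
    mol = rw.GetMol()
    mol.UpdatePropertyCache(strict=False)
    Chem.FastFindRings(mol)
    return mol


def canonical_key(scaffold, level: int) -> ScaffoldKey:
    """Canonical ``(level, key)`` identity for one scaffold object.

    Accepted representations by level: 0 — ignored (root sentinel);
    1 — ring count (int); 2-3 — ring-connectivity ``networkx`` graph with
    per-edge ``strength`` ("strong" encodes as bond order 2, "weak" as 1);
    4-6 — plain ``networkx`` graph (all-carbon, single bonds); 7-8 — RDKit
    molecule (level 8 keeps stereo in the key, level 7 must not carry any).
    The key is invariant under relabeling/reordering of the input graph;
    the empty scaffold (acyclic molecule) maps to ``"-"`` at levels 2-8.
    """
    if level == 0:
        return ScaffoldKey(0, ROOT_KEY)
    if level == 1:
        return ScaffoldKey(1, str(int(scaffold)))
    if level in (7, 8):
        mol: Chem.Mol = scaffold
        if mol.GetNumAtoms() == 0:
            return ScaffoldKey(level, EMPTY_KEY)
        return ScaffoldKey(level, Chem.MolToSmiles(mol))
    graph: nx.Graph = scaffold
    if graph.number_of_nodes() == 0:
        return ScaffoldKey(level, EMPTY_KEY)
    element = 0 if level in (2, 3) else 6
    return ScaffoldKey(level, Chem.MolToSmiles(_graph_to_rwmol(graph, element)))


def parse_key(key: ScaffoldKey):
    """Inverse of :func:`canonical_key`: rebuild the scaffold object.

    Used to verify that every hierarchy level is computable from the level
    below it alone (without the original molecule), and for depicting
    scaffolds in exports.
    """
    level, s = key
    if level == 0:
        return None
    if level == 1:
        return int(s)
    if s == EMPTY_KEY:
        return Chem.Mol() if level >= 7 else nx.Graph()
    if level in (7, 8):
        mol = Chem.MolFromSmiles(s)
        if mol is None:  # frameworks with retained unusual valence
            mol = Chem.MolFromSmiles(s, sanitize=False)
            mol.UpdatePropertyCache(strict=False)
            Chem.FastFindRings(mol)
        return mol
    mol = Chem.MolFromSmiles(s, sanitize=False)
    graph = nx.Graph()
    graph.add_nodes_from(range(mol.GetNumAtoms()))
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if level in (2, 3):
            strength = "strong" if bond.GetBondType() == Chem.BondType.DOUBLE \
                else "weak"
            graph.add_edge(u, v, strength=strength)
        else:
            graph.add_edge(u, v)
    return graph
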