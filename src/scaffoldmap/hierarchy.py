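"""Build, merge, persist, query and annotate the rooted scaffold hierarchy.

The hierarchy is a rooted tree: one virtual root at level 0, eight scaffold
levels (1-8) and molecules conceptually hanging off the level-8 nodes.
Each node stores how many background molecules pass through it and, after
annotation with a user dataset, how many user molecules do.  Per-level
frequency totals always equal the molecule count — every molecule
contributes exactly one scaffold per level.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .chem_io import ROOT_KEY, Molecule, ScaffoldChain, ScaffoldKey
from .engine import scaffold_chain

log = logging.getLogger(__name__)

CSV_COLUMNS = ["level", "key", "parent_key", "background_freq", "child_count"]


@dataclass
class ScaffoldNode:
    key: ScaffoldKey
    parent: ScaffoldKey | None
    background_freq: int = 0
    dataset_freq: int = 0
    children: set[ScaffoldKey] = field(default_factory=set)

    @property
    def child_count(self) -> int:
        return len(self.children)


class Hierarchy:
    """Rooted tree of scaffold nodes, levels 0-8."""

    def __init__(self) -> None:
        root = ScaffoldKey(0, ROOT_KEY)
        self.nodes: dict[ScaffoldKey, ScaffoldNode] = {
            root: ScaffoldNode(root, None)}
        self.root_key = root

    # -- basic queries ----------------------------------------------------

    @property
    def root(self) -> ScaffoldNode:
        return self.nodes[self.root_key]

    @property
    def molecule_count(self) -> int:
        return self.root.background_freq

    @property
    def dataset_count(self) -> int:
        return self.root.dataset_freq

    def __len__(self) -> int:
        return len(self.nodes)

    def __contains__(self, key: ScaffoldKey) -> bool:
        return key in self.nodes

    def __getitem__(self, key: ScaffoldKey) -> ScaffoldNode:
        return self.nodes[key]

    def level_nodes(self, level: int) -> list[ScaffoldNode]:
        return [n for k, n in self.nodes.items() if k.level == level]

    def children(self, key: ScaffoldKey) -> list[ScaffoldNode]:
        return [self.nodes[c] for c in sorted(self.nodes[key].children)]

    def ancestors(self, key: ScaffoldKey) -> list[ScaffoldKey]:
        """Path from the parent of ``key`` up to the root; length == level."""
        if key not in self.nodes:
            raise KeyError(key)
        out = []
        node = self.nodes[key]
        while node.parent is not None:
            out.append(node.parent)
            node = self.nodes[node.parent]
        return out

    def subtree(self, key: ScaffoldKey) -> "Hierarchy":
        """Restriction of the hierarchy to ``key`` and its descendants.

        The returned view is rooted at ``key`` (its ``root_key`` is the
        node itself), so its ``molecule_count`` is the number of molecules
        passing through that scaffold; per-level conservation holds for
        the levels the view spans.
        """
        if key not in self.nodes:
            raise KeyError(key)
        view = object.__new__(Hierarchy)
        view.nodes = {}
        view.root_key = key
        stack = [key]
        while stack:
            k = stack.pop()
            n = self.nodes[k]
            view.nodes[k] = ScaffoldNode(
                k, None if k == key else n.parent,
                n.background_freq, n.dataset_freq, set(n.children))
            stack.extend(n.children)
        return view

    # -- construction -----------------------------------------------------

    def _insert_chain(self, chain: ScaffoldChain, dataset: bool = False) -> None:
        keys = [self.root_key] + sorted(chain)  # levels 0,1..8
        for parent, key in zip(keys, keys[1:]):
            if key not in self.nodes:
                self.nodes[key] = ScaffoldNode(key, parent)
            self.nodes[parent].children.add(key)
        for key in keys:
            node = self.nodes[key]
            if dataset:
                node.dataset_freq += 1
            else:
                node.background_freq += 1

    def validate(self) -> None:
        """Assert the tree and conservation invariants."""
        seen = {self.root_key}
        stack = [self.root_key]
        while stack:
            k = stack.pop()
            for c in self.nodes[k].children:
                assert c not in seen, f"node {c} reached twice"
                assert self.nodes[c].parent == k
                assert c.level == k.level + 1
                seen.add(c)
                stack.append(c)
        assert seen == set(self.nodes), "unreachable nodes"
        for level in range(self.root_key.level, 9):
            nodes = self.level_nodes(level)
            assert sum(n.background_freq for n in nodes) == self.molecule_count
            assert sum(n.dataset_freq for n in nodes) == self.dataset_count


def build_hierarchy(molecules: Iterable[Molecule]) -> Hierarchy:
    """Single pass over a molecule stream; memory scales with distinct
    scaffolds, not molecules.  Duplicate molecules count multiply —
    frequencies are molecule counts, not distinct-compound counts."""
    h = Hierarchy()
    for mol in molecules:
        h._insert_chain(scaffold_chain(mol))
    return h


def merge(a: Hierarchy, b: Hierarchy) -> Hierarchy:
    """Combine two hierarchies built with the same engine configuration.

    Frequencies add and node sets union; associative and commutative, so
    a background can be built in shards and folded together.
    """
    if a.root_key != b.root_key:
        raise ValueError("cannot merge hierarchies with different roots")
    out = Hierarchy()
    for src in (a, b):
        for key, node in src.nodes.items():
            if key not in out.nodes:
                out.nodes[key] = ScaffoldNode(key, node.parent)
            dst = out.nodes[key]
            dst.background_freq += node.background_freq
            dst.dataset_freq += node.dataset_freq
            dst.children |= node.children
    return out


def annotate(background: Hierarchy, molecules: Iterable[Molecule]
             ) -> tuple[Hierarchy, pd.DataFrame]:
    """Overlay a user dataset on a background hierarchy.

    Returns a new hierarchy with ``dataset_freq`` populated (user scaffolds
    missing from the background are added with ``background_freq`` 0) and a
    per-molecule table mapping each user molecule to its chain — the basis
    for molecule-list filtering by scaffold.
    """
    h = merge(background, Hierarchy())
    rows = []
    for mol in molecules:
        chain = scaffold_chain(mol)
        h._insert_chain(chain, dataset=True)
        row = {"id": mol.id, "name": mol.name, "smiles": mol.smiles}
        for k in chain:
            row[f"level{k.level}"] = k.key
        rows.append(row)
    table = pd.DataFrame(rows)
    return h, table


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def export_csv(h: Hierarchy, path: str | Path) -> None:
    """Write the hierarchy as CSV: level, key, parent_key, background_freq,
    child_count.  Dataset frequencies are never persisted — a background
    file describes the background only."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CSV_COLUMNS)
        for key in sorted(h.nodes):
            node = h.nodes[key]
            w.writerow([key.level, key.key,
                        node.parent.key if node.parent else "",
                        node.background_freq, node.child_count])


def load_csv(path: str | Path) -> Hierarchy:
    """Inverse of :func:`export_csv`; a malformed row is a fatal error."""
    h = Hierarchy()
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != CSV_COLUMNS:
            raise ValueError(f"{path}: unexpected header {header!r}")
        for lineno, row in enumerate(reader, start=2):
            try:
                level, key_s, parent_s, freq, child_count = row
                level = int(level)
                freq = int(freq)
                key = ScaffoldKey(level, key_s)
                parent = None if level == 0 else ScaffoldKey(level - 1, parent_s)
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}: malformed row {lineno}: {row!r}") \
                    from exc
            if level == 0:
                h.root.background_freq = freq
                continue
            h.nodes[key] = ScaffoldNode(key, parent, freq)
    # rebuild child links and check referential integrity
    for key, node in h.nodes.items():
        if node.parent is not None:
            if node.parent not in h.nodes:
                raise ValueError(f"{path}: {key} references missing parent")
            h.nodes[node.parent].children.add(key)
    return h
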