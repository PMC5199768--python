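# scaffoldmap

Hierarchical molecular scaffold analysis and treemap visualization of
compound libraries against a background chemical space.

Medicinal chemists group molecules by their *scaffolds* — the core that
remains when functional groups and side chains are stripped away. A single
scaffold definition gives a flat classification; `scaffoldmap` instead
maps every molecule to a chain of **eight nested scaffolds**, from the
fully chemical Bemis–Murcko framework down to the bare ring count, so that
any compound library becomes a rooted tree (a virtual root, eight scaffold
levels, molecules as leaves). A large reference library processed this way
yields a *background hierarchy* — an empirical map of chemical space — and
any user dataset can then be displayed on that map as a squarified
treemap: cell **area** encodes how common a scaffold is in the background,
cell **color** how common it is in the user's data.

## The scaffold hierarchy

Each level is computable from the level below it alone, which makes the
tree largely molecule-independent and precomputable:

| level | name | transformation |
|---|---|---|
| 8 | rings with linkers, stereo | delete side chains (terminal atoms, iteratively); keep surviving stereo |
| 7 | rings with linkers | drop all stereo marks |
| 6 | graph framework | every atom → carbon, every bond → single |
| 5 | contracted linkers | splice out degree-2 non-ring (linker) atoms |
| 4 | ring topology (Oprea) | edge-merge remaining degree-2 vertices, except in triangles |
| 3 | ring connectivity, extended | one vertex per CSSR ring; *strong* edge = rings share a bond (fused), *weak* = shared atom (spiro) or linker-path connection |
| 2 | ring connectivity | strong/weak distinction dropped |
| 1 | ring count | number of CSSR rings |

Ring perception uses the **complete set of smallest rings** (CSSR, the
"relevant cycles": every cycle that is not a sum of strictly shorter
cycles), which unlike SSSR is symmetry-complete — the cube graph has six
4-rings, not an arbitrary five. Acyclic molecules collapse to the empty
scaffold `-` at levels 2–8 and ring count 0. Disconnected compounds are
kept whole: two disconnected rings are a different ring-connectivity
topology than two connected ones.

A tree of height 9 with branching factor 100 holds 100⁹ = 10¹⁸ leaves;
covering a 10⁸-molecule reference space needs only an average branching
factor of 10^(8/9) ≈ 7.7 — the design headroom the eight levels provide.

## Worked example

```python
from rdkit import Chem
from scaffoldmap import Molecule, scaffold_chain

m = Molecule(id="diazepam",
             mol=Chem.MolFromSmiles("CN1C(=O)CN=C(c2ccccc2)c2cc(Cl)ccc21"))
for k in reversed(scaffold_chain(m)):
    print(f"level {k.level}: {k.key}")
```

```
level 8: c1ccc(C2=NCCNc3ccccc32)cc1
level 7: c1ccc(C2=NCCNc3ccccc32)cc1
level 6: C1CCC(C2CCCCC3CCCCC32)CC1
level 5: C1CCC(C2CCCCC3CCCCC32)CC1
level 4: C1CC1C1C2CC21
level 3: **=*
level 2: ***
level 1: 3
```

Reading upwards: diazepam's framework is the benzodiazepine bicycle plus
the pendant phenyl (chlorine and the N-methyl/carbonyl side chains are
gone); it carries no stereo, so level 7 is identical; level 6 forgets
elements and bond orders; nothing contracts at level 5 (the phenyl hangs
by a direct bond, there are no linker atoms); level 4 reduces each ring to
its minimal topology — a triangle fused to a triangle-pair; level 3 shows
three rings, two fused (`=`, strong) and one flexibly attached; level 2
keeps only "three connected rings"; level 1 counts them.

Building a background and rendering a dataset against it from the shell:

```sh
scaffoldmap fixtures --n 1000 --seed 0 --out lib.smi     # synthetic library
scaffoldmap generate --input lib.smi --out background.csv
scaffoldmap stats --background background.csv --top-k 5
scaffoldmap annotate --input subset.smi --background background.csv --out annotated.csv
scaffoldmap render --background background.csv --input subset.smi --out map.svg --depth 2
```

`stats` prints, for the 1000-molecule synthetic library (seed 0):

```
molecules: 1000  distinct scaffolds: 97
 rank key  frequency  frequency_pct  children  coverage_pct
    1   2        458           45.8         2          45.8
    2   1        363           36.3         1          82.1
    3   3         86            8.6         2          90.7
    4   0         48            4.8         1          95.5
    5   4         45            4.5         1         100.0
```

i.e. two-ring compounds dominate (45.8 %), one-ring compounds follow
(36.3 %), and the top five ring counts cover the whole library. Any
SMILES/SDF collection — a vendor catalogue, a corporate registry, a public
database export — can serve as the background; nothing is hard-coded to a
particular source.

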