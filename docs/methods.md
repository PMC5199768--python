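# Methods

This note records the model behind `scaffoldmap`, the numerical and design
choices that were genuinely open, and what the test suite does and does
not demonstrate.

## The hierarchy as a model of chemical space

The package classifies every molecule by a chain of eight scaffolds of
strictly decreasing information content. The guiding requirements are
(1) *tree structure* — two molecules sharing a scaffold at level k share
scaffolds at all levels above, so every node has exactly one parent, and
(2) *level-wise computability* — each scaffold is a function of the
scaffold one level below, never of the original molecule. Property (2) is
what makes a precomputed background hierarchy possible: the tree built
from one library remains valid for any other, and is enforced in the
suite as a functoriality test (recomputing level-k keys from parsed
level-(k+1) keys alone).

The closed-form design numbers: nine levels of branching 100 give
100⁹ = 10¹⁸ leaf slots, while a 10⁸-molecule reference space needs only an
average branching factor of (10⁸)^(1/9) ≈ 7.74. The tree's height is
therefore never the binding constraint; what matters in practice is the
*spread* of branching factors, which the stats module measures (bins,
percentiles, top-k coverage).

## Level semantics and edge cases

**Level 8 (framework).** Standardization first: aromatic perception,
charge neutralization where a proton can be added/removed without
breaking standard valence (fixed charges such as quaternary ammonium are
kept and logged), explicit-H/radical removal, isotope clearing.
Neutralization is delegated to RDKit's `Uncharger`. Side-chain deletion
is iterative removal of terminal heavy atoms to a fixed point, performed
on the kekulized structure so that losing an exocyclic atom of a pushed
aromatic system (e.g. a pyridinone carbonyl) cannot leave an
un-kekulizable ring; aromaticity is re-perceived afterwards. The strict
side-chain definition is used: *every* non-ring, non-linker atom is
removed, including multiply-bonded terminals such as keto oxygens —
keeping them would leave pendant vertices at level 6 that the contraction
levels are defined not to contain. Stereo is conserved exactly as far as
it remains defined: after deletion, stereo perception is re-run and
centers that are still stereogenic keep their configuration; centers
whose defining substituent vanished are cleared.

**Levels 7–6.** Stereo stripping, then the all-carbon single-bond
skeleton. Level 6 is a plain graph from here on; vertex count still
equals the framework's heavy-atom count.

**Level 5.** Linker contraction removes degree-2 vertices that lie on no
cycle. Ring membership is decided once, via bridge edges (an atom is a
ring atom iff it is incident to a non-bridge edge). Two anchors can never
be joined by two parallel linker paths — that would put the linker atoms
on a cycle — and this impossibility is asserted at run time rather than
silently assumed. Branching linker atoms (degree ≥ 3) survive.

**Level 4 (ring topology).** Edge-merging of degree-2 vertices to a fixed
point, skipping vertices whose neighbors are adjacent (the triangle
exception, without which every cycle would collapse entirely). The result
is order-independent; the suite checks it against a brute-force oracle
that contracts in random order and re-derives ring membership from
scratch at every step.

**CSSR.** The complete set of smallest rings is realized as the relevant
cycles: a cycle belongs iff it is not a GF(2)-sum of strictly shorter
cycles, equivalently iff it belongs to some minimum cycle basis. Computed
by enumerating simple cycles up to the longest cycle of one minimum cycle
basis and filtering by linear independence from shorter cycles (bitmask
Gaussian elimination). This reproduces the expected counts on fused,
spiro, bridged and cage systems (cube → six 4-rings where SSSR reports
five) and agrees with RDKit's symmetrized SSSR on all fixture molecules.
On pathological cage graphs any CSSR definition behaves surprisingly;
such inputs are implementation-defined here as exactly the relevant-cycle
set. One consequence found while testing: the *number* of relevant cycles
is not invariant under degree-2 contraction on arbitrary dense graphs
(only the cycle-space dimension is); on molecular frameworks the count is
conserved across levels 6→5→4, and the suite asserts conservation for
molecule-derived graphs while checking contraction correctness on random
graphs as well.

**Level 3.** One vertex per CSSR ring. Strong edge iff two rings share a
graph edge; weak edge iff they share only a vertex or are connected in
the subgraph of linker (bridge) edges. Running the path search in the
bridge-edge subgraph implements the exclusion of ring edges — anthracene
yields a linear 3-path, not a triangle, because the only connections
between the terminal rings run through ring bonds. When a pair qualifies
as both fused and linker-bridged, strong wins (rigid beats flexible).
Ring pairs connected through a linker path that passes a third ring's
atom are treated as connected; the path consists of linker edges only,
which is the stated criterion.

**Levels 2–1.** Strength erasure, then vertex count. The ring count of
the level-4 graph equals that of the framework (see conservation above),
so computing the decomposition once on the smallest graph is safe.

## Canonical keys

Scaffold identity must be invariant under any atom/bond input ordering.
Levels 8–7 use RDKit canonical SMILES (isomeric at level 8). Levels 6–2
are abstract graphs whose vertices can exceed any real valence, so they
are encoded as unsanitized RDKit molecules (implicit-H accounting and
valence checks disabled, ring perception only) and canonicalized the same
way; levels 3–2 use wildcard atoms with bond order 2 for strong and 1 for
weak connectivity. Level 1 is the decimal ring count, the empty scaffold
is `-`, and the root sentinel is `ROOT`. Key invariance is property-tested
under 100 random relabelings.

## Hierarchy, statistics, treemap

Frequencies are molecule counts (duplicates count multiply). Per-level
totals equal the molecule count — conservation is asserted on every
`validate()`. Merging adds frequencies and unions node sets, so sharded
background builds are exact. The CSV schema is
`level,key,parent_key,background_freq,child_count`; dataset frequencies
are never persisted in a background file. Annotation copies the
background, so a background object is never mutated by overlaying a
dataset; user scaffolds absent from the background enter with background
frequency 0 and, in the relative color mode, map to the top of the
gradient (maximally enriched).

Branching bins (1–100, 101–400, 401–1600, >1600) come from square screen
grids (10×10, 20×20, 40×40). Zero-child scaffolds are excluded from the
binning; the bins therefore cover scaffolds *with* children, which in a
hierarchy built from full chains is all of them on levels 0–7.
Percentiles are nearest-rank — reported values are always observed child
counts, never interpolated ones. Top-k tables break frequency ties
lexicographically on the key so output is deterministic.

The squarified treemap follows the classical greedy row construction:
rows are laid along the shorter side of the remaining free rectangle, and
a weight joins the current row only while it strictly improves the row's
worst aspect ratio (ties finalize the row, matching the published
pseudocode). Areas are exactly proportional to weights (conservation
tested to 1e-9 relative on 1,000 random vectors) and the worst aspect
ratio never exceeds the single-strip (slice-and-dice) baseline in the
property tests; this is a heuristic guarantee, not a theorem. Zero-weight
children get no cell rather than an epsilon cell. Color values are
min–max normalized across siblings (local, per-frame scaling keeps each
zoom level informative; global scaling would wash out deep frames). The
color of a non-leaf cell is computed from that node's own frequencies —
how an interactive client might aggregate subtree colors is left open.
The default gradient is white→red; any matplotlib colormap name may be
substituted. SVG output is plain rectangles with text labels and
tooltips, written directly (the format is trivial); `--depth` nests one
layout per level to emulate zoom frames in a static picture.

## Synthetic libraries and their ground truth

The fixture generator composes molecules from ~20 hand-vetted framework
templates — single rings (aromatic, saturated, heteroaromatic), fused
(naphthalene, decalin, indane), bridged (norbornane), spiro, linked pairs
with linkers of length 0–3, a branching three-ring system
(triphenylmethane), a disconnected pair, an angularly attached three-ring
system, the steroid nucleus (gonane), a stereo-bearing fused system
(cis-decalin) and acyclic bodies — decorated with 0–3 random side chains
from a small vocabulary. Template frequencies are weighted so simple
aromatic frameworks dominate, loosely resembling a drug-like screening
library. Each template carries its scaffold chain *specified by hand*:
SMILES for levels 8–7, explicit edge lists for levels 5–4, ring-graph
specs for levels 3–2 and the ring count; only the canonical-key encoder
is shared with the engine, none of the transformations. Since side
chains never alter a framework, these hand-derived chains are exact
ground truth for every generated molecule, which makes hierarchy
statistics exactly checkable.

Default generation parameters (side-chain count 0–3, the template
weights) are fixed in `fixtures.py` and were chosen once for structural
diversity; they are not tuned to any test outcome. What passing on this
library shows: the transformations, keys, hierarchy bookkeeping and
statistics are exact on a structurally diverse desk-scale input. What it
does not show: behavior on registry-scale libraries (tautomers, exotic
cage systems, organometallics, charge-state diversity, 10⁷–10⁸ molecule
throughput). Registry-wide scaffold counts and coverage figures are
snapshot-dependent and are deliberately not reproduced.

## Problem sizes

The test suite uses a 500-molecule session fixture library, 500 random
contraction graphs (≤ 20 vertices), a 1,000-molecule functoriality
library and 1,000-vector treemap property sweeps; the acceptance script
builds a 10,000-molecule background and annotates a 1,000-molecule
subset. These sizes exercise every code path with exact oracles while
keeping a full run in the low tens of seconds.

## Known limitations

- Canonical keys are RDKit-canonical; they are stable across runs and
  input orderings but not interchangeable with keys produced by other
  cheminformatics toolkits (aromaticity and neutralization models
  differ).
- Aromatic flags are kept at level 7 rather than kekulized; this affects
  key strings, not topology.
- CSSR on dense cage graphs is implementation-defined (relevant cycles).
- InChI/CML input, interactive browsing, and client–server operation are
  out of scope; the SVG/JSON exports carry everything a front end needs
  to implement zooming.
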