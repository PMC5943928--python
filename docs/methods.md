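# Methods

## Scope and model

The package annotates, detects and counts *localized atomic
interactions* in molecular configurations: hydrogen bonds (HB) between
carboxylic-acid groups and hydrophobic contacts (HP) between primary
alkyl (methyl) carbons, the two networks that dominate a carboxylic-acid
liquid. Interaction *detection* is purely geometric; interaction
*identity* (which atoms, in which functional groups, with which
exclusivity) is carried by DANAI expressions over DL_F-style atom
labels. Ten macro-interaction type tokens (DD, HB, ID, HP, EI, CD, PS,
PD, PT, PI) parse; detectors and matchers exist for HB and HP only, and
delocalised-π group tokens (`<C6>`, `<C501>`) parse but are rejected by
the matcher as unsupported.

## Atom typing

A DL_F-lite perceiver assigns labels from explicit covalent topology
(elements + bonds + molecule membership, supplied as a JSON sidecar):

* carboxylic acid (CGI 20): a carbon bonded to two oxygens of which
  exactly one is terminal (C20, O20E) and the other carries exactly one
  hydrogen (O20L, H20O). Ambiguous oxygen roles (both terminal, both
  protonated) are an error, not a guess.
* alkane primary carbon (CGI 1): a four-coordinate carbon with exactly
  one heavy neighbour (C1p).

Carbonyl versus hydroxyl oxygen is decided by connectivity alone because
the sidecar carries no bond orders. Bond input is explicit by design —
force-field topologies should come from the force-field builder; a
covalent-radii (+0.4 Å slack) guesser exists for fixture convenience
only. The group registry ships the four documented CGI values (alkane 1,
benzene 6, carboxylic_acid 20, pyridine 501); only the first and third
have full templates, and the alcohol group is omitted because its index
and labels are not documented — the registry is open for users to add
it.

## Expression semantics

The grammar (EBNF in `danai/notation.py`) tokenises atoms by longest
match (`c1p` is one token), resolves abbreviated labels against the
macro-interaction's group indices, and accepts `o`/`O` as an alias of
the hydroxyl oxygen `oL` (the form the wildcard expansion `oE#h` ≡
`oE-c-o-h` uses). Structure-class validation is strict: L requires the
group-level graph to be a simple path, R a single cycle with the
first/last token denoting one identical atom, J a tree with all
branching concentrated in exactly one atom carrying ≥ 2 non-bonded
edges; a mismatch is an error because the class is part of the
expression's meaning. Chemical-group instances are the connected
components of the covalent-plus-wildcard subgraph, and their number must
equal the declared count `a`.

Wildcard edges expand to the group template's unique shortest covalent
path between the flanking atoms — in relaxed (lowercase) form for `#`,
strict (uppercase) for `@`. Branches nest at most one level; deeper
nesting is rejected rather than guessed, as is a wildcard opening or
closing a branch.

`canonical_string` serialises a motif deterministically: all admissible
main-chain walks (simple paths, or the cycle for ring motifs) are
enumerated, pendant chains become branches, and the most linear,
lexicographically smallest rendering wins, so isomorphic motifs —
including reversals — produce byte-identical strings that re-parse to
isomorphic motifs. Shapes that would need nested branches are not
serialisable and raise; no expression in the supported interaction
families needs them.

## Matching semantics

A match is an injective map from motif nodes to atoms preserving labels,
covalent edges (to topology bonds), non-bonded edges (to detected
interaction edges), and group structure (one motif instance into one
group occurrence, distinct instances to distinct occurrences). Letter
case gates exclusivity **per atom**: an uppercase node's atom must have
frame interaction degree — of the motif's macro type only — exactly
equal to the node's non-bonded degree in the motif; a lowercase node is
unconstrained beyond its written edges. HB degrees never constrain HP
exclusivity and vice versa, the two networks being independent. A
consequence worth spelling out: in a head-to-tail chain A→B→C, *both*
bonded pairs match `[L2]OL-H:OE-C`, because the middle molecule's second
interaction runs through atoms the expression does not mention; strict
exclusivity is a property of the written atoms, not of the whole
molecule. Expressions that do constrain the rest of the group write it
with `@` (e.g. `oE@h` ≡ `oE-C-O-h`).

Counting conventions, the most consequential interpretation in the
package:

* **L, R (and C) classes** count distinct matches modulo the motif's
  automorphism group — an unordered chain or cycle counts once (the
  cyclic dimer `[R2]` is one occurrence, not two), but two chains
  sharing a middle molecule are two matches; overlapping matches are
  deliberately not merged, since short motifs are expected to be subsets
  of longer structures.
* **J classes** count distinct assignments of the junction atom only:
  `[J4]c1p:c1p(:c1p):c1p` is the number of methyl carbons with at least
  three (relaxed) methyl neighbours, not the number of ways of choosing
  them. This split reproduces both natural readings — per-centre counts
  for junctions, per-path counts for chains (a star of four methyls
  yields `[J4]` = 1 and `[L3]` = 3).

The production counter runs on networkx's VF2 subgraph-monomorphism
machinery with the degree and group constraints layered on; the
embedding total is divided by the automorphism order (embeddings fall in
free orbits of the automorphism group, so the division is exact and is
asserted). `brute_force_count` re-implements the same contract as a
plain recursive enumeration over label-compatible atoms with no
ordering heuristics and no acceleration, refuses systems beyond 80
atoms, and serves as the independent oracle in the tests.

## Detection

Hydrogen bond: H···acceptor minimum-image distance ≤ d (default 2.5 Å)
**and** donor–H···acceptor angle with H at the apex ≥ θ (default 120°),
both inclusive; donor and acceptor must belong to different group
instances, which excludes the intramolecular O–H···O of one COOH but
allows the two groups of a diacid. One hydrogen may carry several bonds
— bifurcation is a first-class outcome, and exclusivity belongs to
matching, not detection. Whether a hydroxyl oxygen may accept while its
own hydrogen donates is left to geometry (it may). Hydrophobic contact:
intermolecular C1p pair within 4.5 Å. Boxes are orthorhombic
(minimum-image); frames without a box are open clusters. Pair search
uses a periodic k-d tree, with the all-pairs path kept as the reference
(`method="brute"`) and asserted equal in the tests. Inclusive threshold
comparisons carry a 10⁻⁹ Å tolerance so exactly-at-threshold geometries
are not lost to rounding. The radial distribution function g(r)
normalises shell pair counts by the uniform expectation in the box and
is the standard first-peak sanity check for the HB distance criterion.

## Statistics

Count series use population averages over frames (divide by T), matching
the ensemble-average notation; reported σ is likewise the population SD
— at T in the thousands the sample/population difference is negligible,
but the choice is fixed and documented. Correlation of a constant series
is undefined and raised as an error, never silently zero. The printed
percentage ratios round half-away-from-zero, the convention that
reproduces printed values like 1.5 %, 72 % and 0.18 % from their mean
counts.

## Synthetic configurations

The generator emulates the study system — pure ethanoic acid — as rigid
idealised molecules (C–C 1.50 Å, C=O 1.21 Å, C–O 1.34 Å, O–H 0.97 Å,
C–H 1.09 Å, trigonal 120° at the carboxyl carbon, tetrahedral
elsewhere; syn and anti hydroxyl conformers):

* hydrogen-bonded chains (head-to-tail H···O20E or tail-to-tail
  H···O20L, 1.8 Å, 180° at H), successive molecules twisted 120° about
  the chain axis so nothing else meets the criteria;
* the classic cyclic dimer (two reciprocal H···O20E bonds, C2 symmetry,
  syn conformer);
* methyl clusters with a prescribed contact topology (chains or stars at
  4.0 Å spacing, clusters 12 Å apart, carboxyls pointing away);
* random rigid packings in a periodic cubic box by rejection sampling
  with Haar-uniform orientations, reproducible under a fixed seed. The
  default inter-molecular atom separation of 1.3 Å is the largest at
  which insertion stays feasible at the liquid's density (674 molecules
  per (40 Å)³, 84 per (20 Å)³ at 1.05 g/cm³).

Every constructed fixture audits its advertised HB and HP edge sets
through the full typing → detection pipeline after placement and fails
loudly on any discrepancy. What the pseudo-liquid does *not* emulate is
thermodynamics: packings are random, not relaxed, so absolute counts of
the long-trajectory study (which required nanoseconds of force-field
dynamics) are out of reach by design, and passing tests demonstrate
correctness of the machinery, not agreement with equilibrium structure.

## Problem sizes and numerical choices

The oracle-equivalence suite runs all sixteen documented HB/HP
expressions against the exhaustive oracle on fifty seeded five-molecule
pseudo-liquids (40 atoms each, dense enough that about a tenth of the
checks have non-zero counts); monotonicity sweeps use 25–30-molecule
packings; the acceptance script uses 200 frames of a 20-molecule box.
These sizes were chosen as the smallest at which every behaviour the
suite asserts is actually exercised. Ties in cluster ordering break by
smallest member id; automorphism-division remainders, constant series,
infeasible packings and ambiguous typings all raise rather than warn.

## Known limitations

No triclinic boxes, no energetic or orbital hydrogen-bond definitions,
no donor–acceptor-distance criterion variant, no aromatic perception or
π-stacking matching, no maximal-substructure mining, no time-lagged
correlations or block-error analysis, no compressed trajectory formats.
The `[C...]` complex class imposes connectivity only — no constraint
beyond "not L/R/J" is defined for it anywhere, so none is invented.
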