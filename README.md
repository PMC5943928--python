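# danai

Annotation, detection and counting of localized atomic interactions —
hydrogen bonds and hydrophobic contacts — in molecular configurations and
trajectories.

## The problem

Molecular-dynamics trajectories of liquids contain rich local interaction
structure (head-to-tail hydrogen-bonded chains, bifurcations, cyclic
dimers, hydrophobic clusters) that radial distribution functions average
away and pictures cannot quantify. The DANAI notation closes that gap: a
compact text expression names one *interaction motif*, and a matcher
counts its occurrences in every frame, so "how often does the carbonyl
oxygen accept two hydrogens at once?" becomes a query rather than a
figure.

An interaction is specified at two levels:

* **macro-interaction** `A_CGI1_CGI2` — the interaction type between two
  chemical groups (CG), identified by their DL_F Chemical Group Indices:
  `HB_20_20` is hydrogen bonding between two carboxylic-acid groups
  (CGI 20), `HP_1_1` a hydrophobic contact between alkane groups (CGI 1).
* **micro-interaction** `[Sa]atomic_interaction` — one local mode, as a
  small labelled graph. `S ∈ {J, R, L, C}` classifies the topology
  (junction, ring, linear, complex) and `a` counts the CG instances.
  Atom tokens are DL_F labels (`C20`, `O20E`, `O20L`, `H20O`, `C1p`),
  abbreviated in context to `c`, `oE`, `oL`, `h`, `c1p`. `:` is a
  non-bonded interaction, `-` a covalent bond, `#`/`@` stand for the rest
  of the group (`oE#h` ≡ `oE-c-o-h`), `(X)` is a branch, and **letter
  case is semantic**: an uppercase atom must carry *exactly* the
  non-bonded interactions written for it (strict), a lowercase atom *at
  least* those (relaxed). So `[L2]OL-H:OE-C` counts head-to-tail hydrogen
  bonds whose written atoms take part in no other bond, while
  `[L2]oL-h:oE-c` counts every one.

Detection is geometric: an H···acceptor distance ≤ *d* = 2.5 Å with a
donor–H···acceptor angle (H at apex) ≥ *θ* = 120° defines a hydrogen
bond; a methyl-carbon pair within 4.5 Å defines a hydrophobic contact;
periodic boxes use the minimum-image convention. Per-expression counts
C_x(t) over frames t form series whose inter-relationships are measured
by the normalised covariance

    C_{x−y} = ⟨ΔC_x·ΔC_y⟩ / √(⟨ΔC_x²⟩⟨ΔC_y²⟩),   ΔC_i = C_i − μ_i,

with ⟨·⟩ the average over frames: 1.0 for fully correlated expressions,
0.0 for uncorrelated ones.

The package provides the expression parser with canonicalisation, a
DL_F-lite atom typer (carboxylic-acid and alkane groups from explicit
covalent topology), XYZ/PDB trajectory I/O, the HB/HP detectors, a
subgraph-isomorphism motif counter with a brute-force oracle, hydrophobic
cluster tracing, count-series statistics, a synthetic-configuration
generator for all of the above, and a thin `danai` command-line front
end.

## A worked example

```python
from danai import (assign_types, build_interaction_graph, count_motif,
                   expand_wildcards, make_hb_chain, parse_macro, parse_micro)

hb = parse_macro("HB_20_20")
topology, frame = make_hb_chain(3, "head_to_tail")   # 3 molecules, 2 bonds
typed = assign_types(topology)
graph = build_interaction_graph(frame, typed, topology, "HB")
for expr in ("[L2]oL-h:oE-c", "[L2]OL-H:OE-C", "[L3]oL-h:oE#h:oE-c"):
    motif = expand_wildcards(parse_micro(expr, hb))
    print(expr, count_motif(motif, graph, typed, topology))
```

prints

```
[L2]oL-h:oE-c 2
[L2]OL-H:OE-C 2
[L3]oL-h:oE#h:oE-c 1
```

— the chain holds two head-to-tail hydrogen bonds (each one a relaxed
`[L2]` match), both of which are exclusive at the four written atoms
(strict `[L2]`), and together they form one three-group linear structure
(`[L3]`). On the cyclic dimer fixture the same code counts
`[R2]c-oL-h:oE#h:oE-c` once: the double hydrogen bond ring, counted
modulo its own symmetry.

The `examples/` directory has one short script per capability
(`parse_and_canonicalize.py`, `detect_and_count.py`,
`liquid_statistics.py`); each prints what it computes and says what the
numbers mean. The same pipeline runs from the shell:

```sh
danai generate --fixture liquid --n 84 --box 20 --out scratch/liq
danai run config.yaml     # counts.csv, summary.csv, correlation.csv, clusters.txt
```

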