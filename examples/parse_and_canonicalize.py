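"""Parse interaction expressions and print their canonical forms.

Each micro-interaction expression is parsed into a labelled motif graph;
wildcards (#/@) are expanded against the carboxylic-acid group template,
and the motif is re-serialised canonically, so differently written but
equivalent expressions collapse to one string.
"""
from danai import canonical_string, expand_wildcards, parse_macro, parse_micro

hb = parse_macro("HB_20_20")

for expr in (
    "[L2]oL-h:oE-c",  # relaxed head-to-tail hydrogen bond
    "[L2]c-oE:h-oL",  # the same motif written in reverse
    "[L2]OL-H:OE-C",  # strict variant: written atoms must be exclusive
    "[L3]oL-h:oE#h:oE-c",  # chain of two head-to-tail bonds, using a wildcard
    "[J3]oL-h:oE(c):h-oL",  # bifurcated carbonyl oxygen
    "[R2]c-oL-h:oE#h:oE-c",  # the classic cyclic dimer
):
    motif = expand_wildcards(parse_micro(expr, hb))
    print(
        f"{expr:26s} -> class {motif.structure_class}{motif.cg_count}, "
        f"{motif.n_nodes} atoms, {len(motif.nonbond_edges)} non-bonded edge(s), "
        f"canonical {canonical_string(motif)}"
    )

# The canonical form identifies equivalent expressions: the first two lines
# print the same canonical string, while the strict variant differs because
# letter case is part of the motif's meaning.
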