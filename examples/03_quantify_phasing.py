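"""Quantify phased small-RNA expression over the nine partitions.

Simulates a sequencing library with known per-partition proportions (miR
dominant, ACR3 minor, some leak), maps it back, and compares recovered
normalized abundances with the planted truth; then shows the mutant /
wild-type ratio conventions on a planted ACR3 induction.
"""
from phasemir import quantify, ratio_mut_wt
from phasemir.simulate import HairpinSpec, LibrarySpec, gen_hairpin, gen_library

planted = gen_hairpin(HairpinSpec(seed=5))
seq = planted.hairpin.seq
schemes = {seq.id: planted.scheme}

wt_lib, truth = gen_library(planted, LibrarySpec(depth=20_000, seed=1), "wt")
expr_wt = quantify([wt_lib], [seq], schemes)

print(f"{'partition':<6} {'planted':>9} {'recovered':>10}")
totals = expr_wt.groupby("partition")["unique"].sum()
for name, expected in truth.items():
    print(f"{name:<6} {expected:>9.0f} {totals.get(name, 0.0):>10.1f}")
# Recovered abundances equal the planted read counts exactly: mapping is
# perfect-match and every generated read overlaps its partition >= 80%
# (leak reads deliberately straddle partition boundaries below 80%).

mut_spec = LibrarySpec(
    proportions=(("miR", 0.45), ("miR*", 0.05), ("ACR5", 0.05),
                 ("ACR3", 0.42), ("leak", 0.03)),
    depth=20_000, seed=2,
)
mut_lib, _ = gen_library(planted, mut_spec, "mut")
expr_mut = quantify([mut_lib], [seq], schemes)
ratios = ratio_mut_wt(expr_mut, expr_wt)
print("\nmutant / wild-type ratios (max-possible abundances):")
for _, row in ratios.iterrows():
    flag = f" [{row.flag}]" if row.flag else ""
    print(f"  {row.partition:<6} {row.ratio:>6.2f}{flag}")
# The planted mutant shifts output toward the ACR3 miRNA (ratio >> 1) while
# the miR itself drops; partitions absent in both genotypes report 1.0 with
# an 'absent' flag rather than a meaningless quotient.
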