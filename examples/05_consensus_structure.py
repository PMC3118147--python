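"""Consensus sequence, information content and covariation pairs.

Evolves a 20-row structural alignment with a planted 15-pair helix under
compensatory selection, filters gappy columns, and detects the consensus
base pairs with their covariation classes.
"""
import numpy as np

from phasemir.consensus import StructuralAlignment, consensus_result, consensus_dotbracket
from phasemir.phylo.models import SubstitutionModel
from phasemir.phylo.trees import random_unrooted_topology
from phasemir.simulate import EvolSpec, evolve, paired_doublet_freqs

rng = np.random.default_rng(3)
tree = random_unrooted_topology(
    [f"sp{i}" for i in range(20)], rng, lambda: float(rng.exponential(0.1))
)
pairs = tuple((i, 59 - i) for i in range(15))
model = SubstitutionModel(doublet_freqs=paired_doublet_freqs())
rows = evolve(EvolSpec(tree, model, 60, pairs, seed=4, root_pairs_canonical=True))

aln = StructuralAlignment(tuple(sorted(rows)), tuple(rows[k] for k in sorted(rows)))
result = consensus_result(aln)

print("consensus structure:", consensus_dotbracket(result))
print("planted helix      :", "(" * 15 + "." * 30 + ")" * 15)
print(f"\n{'pair':<10} {'support':>8} {'types':>6}  class")
for p in result.pairs:
    print(f"({p.i:>2},{p.j:>3})  {p.support:>8.2f} {p.pair_types:>6}  {p.klass}")
mean_ic = float(np.mean(result.information))
print(f"\nmean column information content: {mean_ic:.2f} bits")
# 'covarying' pairs show two or more canonical pair types across rows —
# compensatory substitutions that preserve pairing, the classical evidence
# for a conserved secondary structure.  The planted helix is recovered in
# full; the short extra pairs inside the loop are chance covariation among
# only 20 phylogenetically correlated rows and dissolve at larger sizes.
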