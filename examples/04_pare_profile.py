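"""Profile degradome (PARE) cleavage over a precursor context.

Simulates uncapped-5'-end tags with cleavage hot-spots at the planted
duplex boundaries, builds the TP10M profile, aggregates two samples, and
reports the modal cleavage site.
"""
import numpy as np

from phasemir.pare import aggregate, profile
from phasemir.simulate import HairpinSpec, gen_hairpin, gen_pare

planted = gen_hairpin(HairpinSpec(seed=9))
target = planted.hairpin.seq
acr3_start = planted.acr3[0]
mir_start = planted.mir[0]

profiles = []
for s, depth in ((0, 40_000), (1, 25_000)):
    lib, _ = gen_pare(
        target, {acr3_start: 0.6, mir_start: 0.3, 20: 0.1}, depth, seed=s,
        sample_id=f"sample{s}",
    )
    profiles.append(profile(lib, [target]))

total = aggregate(profiles)
arr = total.max_possible[target.id]
print("position  TP10M (total over samples)")
for pos in np.nonzero(arr)[0]:
    mark = " <- modal" if pos == total.modal_site(target.id) else ""
    print(f"{pos:>8}  {arr[pos]:>12.1f}{mark}")
print(f"\nACR3 5' end at {acr3_start}, miR 5' end at {mir_start}")
# The modal site is the most frequently sequenced uncapped 5' end across
# samples — here the planted dominant cut at the ACR3 miRNA 5' boundary,
# the signature of loop-to-base phased processing.
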