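"""Reference mature miRNA sequences of the MIR159/319 family (miRBase).

The two founding members in Arabidopsis thaliana; both are 21 nt and share
17 identical nucleotides, the similarity that groups MIR159 and MIR319
into one family despite their distinct targets.
"""

ATH_MIR159A = "UUUGGAUUGAAGGGAGCUCUA"
ATH_MIR319A = "UUGGACUGAAGGGAGCUCCCU"

MATURE_MIRNAS = {
    "ath-miR159a": ATH_MIR159A,
    "ath-miR319a": ATH_MIR319A,
}
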