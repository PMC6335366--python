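# Secondary-structure propensity: group1 = helix, group2 = strand,
# group3 = coil.
1	EALMQKRH
2	VIYCWFT
3	GNPSD
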