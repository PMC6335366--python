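# Surface tension: group1 = -0.20 to 0.16, group2 = -0.52 to -0.30,
# group3 = -2.46 to -0.98 (dyne/cm).
1	GQDNAHR
2	KTSEC
3	ILMFPWYV
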