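# Polarizability: group1 = 0-0.108, group2 = 0.128-0.186,
# group3 = 0.219-0.409.
1	GASDT
2	CPNVEQIL
3	KMHFRYW
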