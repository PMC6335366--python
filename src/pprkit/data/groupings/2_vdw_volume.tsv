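# Normalized van der Waals volume: group1 = 0-2.78, group2 = 2.95-4.0,
# group3 = 4.03-8.08 (A^3, normalized).
1	GASTPDC
2	NVEQIL
3	MHKFRYW
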