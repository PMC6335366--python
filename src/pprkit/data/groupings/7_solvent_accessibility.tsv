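# Solvent accessibility: group1 = buried, group2 = exposed,
# group3 = intermediate.
1	ALFCGIVW
2	RKQEND
3	MPSTHY
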