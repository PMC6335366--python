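# Hydrophobicity partition used by composition/transition/distribution
# descriptors: group1 = polar, group2 = neutral, group3 = hydrophobic.
1	RKEDQN
2	GASTPHY
3	CLVIMFW
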