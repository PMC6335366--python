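# Charge at physiological pH: group1 = positive, group2 = neutral,
# group3 = negative.
1	KR
2	ANCQGHILMFPSTWYV
3	DE
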