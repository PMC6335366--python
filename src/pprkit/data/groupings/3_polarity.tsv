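# Polarity: group1 = 4.9-6.2, group2 = 8.0-9.2, group3 = 10.4-13.0
# (Grantham-type polarity values).
1	LIFWCMVY
2	PATGS
3	HQRKNED
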