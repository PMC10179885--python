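source	db	share_pct
table3	0	1.3
table3	1	37.9
table3	2	43.1
table3	3	17.7
table4	0	2.5
table4	1	17.0
table4	2	65.3
table4	3	15.2
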