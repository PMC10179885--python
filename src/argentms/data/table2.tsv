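system	temp_c	db	rt_min
I	15	0	6.7
I	15	1	28.1
I	15	2	66.1
I	15	3	66.1
I	25	0	6.5
I	25	1	16.0
I	25	2	61.0
I	25	3	66.5
I	35	0	6.5
I	35	1	16.5
I	35	2	54.5
I	35	3	60.1
II	15	0	6.5
II	15	1	16.5
II	15	2	61.1
II	15	3	64.1
II	25	0	6.5
II	25	1	16.5
II	25	2	54.7
II	25	3	58.2
II	35	0	6.6
II	35	1	17.0
II	35	2	52.2
II	35	3	56.2
III	15	0	6.5
III	15	1	22.9
III	15	2	74.1
III	15	3	130.1
III	25	0	6.4
III	25	1	18.9
III	25	2	65.3
III	25	3	115.4
III	35	0	6.3
III	35	1	17.9
III	35	2	59.3
III	35	3	102.5
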