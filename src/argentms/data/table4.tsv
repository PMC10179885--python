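printed_id	rt_min	cn	db	rel_area_pct
1	6.47	63	0	1.4
3	6.49	62	0	1.0
4	6.49	61	0	0.8
5	6.49	60	0	1.2
6	6.50	59	0	0.8
7	6.50	58	0	1.1
7	6.50	57	0	0.9
8	6.50	56	0	1.2
9	6.51	55	0	0.8
10	6.51	54	0	1.1
11	6.51	53	0	0.7
12	6.51	52	0	1.3
13	6.51	51	0	1.0
14	6.52	50	0	1.6
15	6.52	49	0	1.3
16	6.52	48	0	1.8
17	6.52	47	0	1.8
18	6.52	46	0	2.5
19	6.52	45	0	4.3
20	6.52	44	0	17.8
21	6.54	43	0	6.3
22	6.54	42	0	25.0
23	6.54	41	0	2.8
24	6.54	40	0	4.4
25	6.55	39	0	0.9
26	6.58	30	0	0.7
27	6.59	29	0	6.6
38	6.59	28	0	1.4
29	6.59	27	0	1.5
33	6.59	26	0	5.2
31	6.59	25	0	1.0
32	29.11	43	1	40.8
33	29.14	27	1	0.4
34	29.23	41	1	50.6
35	29.24	40	1	1.6
36	29.90	27	1	0.3
37	29.98	45	1	2.3
38	30.20	27	1	4.0
39	66.14	29	2	0.4
40	66.19	28	2	0.3
41	66.38	27	2	99.3
42	117.31	45	3	3.1
43	118.01	43	3	71.6
44	118.97	41	3	25.3
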