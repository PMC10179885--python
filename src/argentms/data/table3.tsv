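printed_id	rt_min	cn	db	rel_area_pct
1	6.45	49	0	5.9
2	6.45	48	0	1.4
3	6.48	47	0	11.3
4	6.48	46	0	2.0
5	6.50	45	0	11.3
6	6.50	44	0	2.0
7	6.50	43	0	7.1
8	6.50	42	0	1.9
9	6.50	41	0	2.4
10	6.50	40	0	1.3
11	6.50	39	0	1.7
12	6.50	38	0	1.2
13	6.50	37	0	1.2
14	6.50	36	0	1.1
15	6.52	35	0	2.0
16	6.52	34	0	1.6
17	6.54	33	0	5.4
18	6.54	32	0	6.0
19	6.56	31	0	5.4
20	6.56	30	0	13.1
21	6.56	29	0	4.8
22	6.56	28	0	4.8
23	6.56	27	0	2.9
24	6.56	26	0	2.3
25	30.28	47	1	3.9
26	30.34	46	1	0.6
27	30.36	45	1	5.8
28	30.50	44	1	0.8
29	30.50	43	1	5.1
30	30.67	42	1	11.7
31	30.73	40	1	10.7
32	30.86	41	1	4.1
33	30.86	40	1	8.7
34	30.93	38	1	7.2
35	30.95	39	1	12.1
36	31.04	38	1	5.0
37	31.17	37	1	11.8
38	31.19	36	1	2.4
39	31.30	35	1	1.6
40	31.38	34	1	0.8
41	31.46	33	1	0.5
42	31.46	32	1	1.2
43	31.61	31	1	2.0
44	31.69	30	1	0.4
45	31.73	28	1	0.4
46	31.77	29	1	2.1
47	31.92	27	1	1.3
48	55.38	45	2	0.6
49	62.18	41	2	0.1
50	62.77	39	2	0.2
51	62.93	41	2	0.4
52	63.53	43	2	0.1
53	63.60	39	2	1.6
54	63.75	45	2	0.2
55	63.91	41	2	1.1
56	64.25	37	2	0.2
57	64.34	43	2	0.3
58	64.36	39	2	1.4
59	64.51	45	2	0.4
60	64.80	41	2	0.4
61	65.03	37	2	0.3
62	65.05	43	2	0.9
63	65.07	46	2	0.3
64	65.22	39	2	0.5
65	65.55	44	2	0.5
66	65.71	37	2	0.1
67	65.71	41	2	1.8
68	65.86	43	2	1.7
69	66.17	39	2	0.4
70	66.26	42	2	0.6
71	66.26	46	2	1.0
72	66.42	41	2	3.9
73	66.48	45	2	1.7
74	66.82	44	2	2.3
75	66.84	40	2	0.2
76	67.12	43	2	8.0
77	67.16	39	2	1.7
78	67.45	37	2	0.1
79	67.45	42	2	3.1
80	67.63	41	2	22.8
81	67.97	40	2	1.7
82	68.27	39	2	10.4
83	68.47	38	2	0.1
84	68.81	38	2	0.1
85	68.85	46	2	0.6
86	69.12	37	2	0.8
87	69.43	45	2	0.2
88	69.64	44	2	1.7
89	70.13	43	2	0.8
90	70.37	42	2	18.1
91	70.73	41	2	2.5
92	70.86	40	2	0.4
93	71.23	39	2	2.6
94	71.32	40	2	0.6
95	71.74	38	2	0.2
96	71.90	37	2	0.2
97	99.90	47	3	0.6
98	100.73	47	3	0.6
99	101.33	45	3	1.3
100	101.53	47	3	3.0
101	102.12	45	3	1.7
102	102.58	47	3	0.9
103	103.01	45	3	7.5
104	103.5	43	3	0.9
105	103.69	44	3	0.6
106	103.84	45	3	4.2
107	104.44	47	3	0.4
108	104.55	43	3	22.0
109	104.55	44	3	0.4
110	104.94	45	3	1.2
111	105.10	41	3	0.6
112	105.18	42	3	0.6
113	105.20	43	3	13.0
114	105.49	47	3	0.7
115	105.92	45	3	0.5
116	106.03	42	3	0.5
117	106.23	43	3	1.6
118	106.83	41	3	13.9
119	106.97	45	3	1.9
120	107.30	49	3	0.4
121	107.52	43	3	1.9
122	107.86	41	3	2.6
123	107.90	45	3	0.8
124	108.60	43	3	3.9
125	108.94	39	3	0.4
126	108.97	41	3	0.5
127	109.43	39	3	0.3
128	109.52	43	3	1.4
129	110.31	41	3	4.2
130	110.77	43	3	0.4
131	111.37	41	3	2.0
132	112.33	41	3	0.9
133	113.05	39	3	0.7
134	113.76	41	3	0.3
135	114.17	39	3	0.5
136	114.21	43	3	0.2
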