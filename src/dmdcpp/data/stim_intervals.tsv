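subject_id	group	onset	offset
1	AD	3.80	67.46
2	AD	16.89	105.14
3	AD	0.03	43.93
4	AD	15.35	103.34
5	AD	5.37	83.76
6	AD	14.37	118.39
7	AD	17.39	104.14
8	AD	15.57	102.07
9	AD	21.89	104.33
10	AD	15.08	93.16
11	AD	13.99	102.49
12	AD	2.99	84.01
13	AD	17.18	105.55
14	AD	10.05	97.89
15	AD	0.45	28.34
16	AD	5.05	95.04
17	AD	19.54	106.29
18	AD	24.73	114.72
19	AD	0.68	90.67
20	AD	0.95	89.95
21	AD	18.10	55.15
22	AD	4.05	89.44
23	AD	2.92	64.13
24	AD	6.33	69.09
25	AD	3.81	73.80
26	AD	12.33	80.32
27	AD	4.97	92.47
28	AD	3.89	55.05
29	AD	26.26	90.77
30	AD	1.59	71.08
31	AD	6.77	74.77
32	AD	2.79	67.79
33	AD	25.86	94.77
34	AD	15.22	74.24
35	AD	18.33	98.75
36	AD	5.32	74.32
37	CN	6.48	76.47
38	CN	14.82	79.02
39	CN	14.94	162.02
40	CN	0.52	59.34
41	CN	19.09	107.59
42	CN	16.49	106.49
43	CN	7.25	156.29
44	CN	9.52	95.68
45	CN	1.51	111.43
46	CN	14.29	104.28
47	CN	14.33	103.83
48	CN	4.57	92.76
49	CN	27.09	113.70
50	CN	9.34	92.11
51	CN	12.25	100.75
52	CN	2.08	91.07
53	CN	9.55	94.01
54	CN	3.83	147.79
55	CN	15.39	91.90
56	CN	17.39	106.14
57	CN	0.06	68.21
58	CN	0.05	52.68
59	CN	0.45	54.49
60	CN	0.74	126.97
61	CN	6.05	72.80
62	CN	16.58	86.07
63	CN	2.74	69.16
64	CN	0.03	23.48
65	CN	0.03	18.26
66	FTD	1.07	71.40
67	FTD	16.01	98.93
68	FTD	0.30	76.82
69	FTD	14.25	96.26
70	FTD	7.11	97.10
71	FTD	3.88	86.16
72	FTD	0.95	89.94
73	FTD	18.57	102.07
74	FTD	4.23	91.69
75	FTD	12.63	107.28
76	FTD	10.85	87.56
77	FTD	8.49	98.48
78	FTD	8.11	37.61
79	FTD	14.16	81.65
80	FTD	8.06	71.81
81	FTD	21.40	85.26
82	FTD	3.81	69.06
83	FTD	1.40	65.90
84	FTD	2.29	67.62
85	FTD	27.02	92.02
86	FTD	9.73	73.93
87	FTD	5.51	71.77
88	FTD	56.91	122.91
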