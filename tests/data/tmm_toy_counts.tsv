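73	62	336
38	145	208
38	51	256
97	22	368
96	38	1072
26	15	720
75	33	680
63	103	192
27	10	88
112	52	568
55	118	62
26	89	21
29	33	88
69	33	37
28	60	78
33	41	34
39	20	89
38	33	30
23	38	85
32	24	44
47	48	68
38	46	32
60	83	43
55	56	52
26	25	37
65	40	57
68	40	43
32	43	11
85	55	44
18	57	75
69	59	43
75	22	35
66	37	72
30	53	36
41	71	79
36	54	32
33	27	51
75	64	57
39	62	70
59	78	72
35	63	43
83	60	37
26	49	73
29	26	36
65	60	33
56	99	56
59	53	42
24	53	66
19	31	61
42	37	52
34	48	72
38	20	54
43	23	21
52	82	42
70	41	74
22	21	58
32	21	38
77	11	41
37	35	38
24	14	24
19	66	18
18	23	20
106	44	114
46	21	29
71	24	64
52	54	29
37	53	75
96	56	56
35	62	28
55	36	32
44	61	41
59	45	44
37	84	93
51	41	40
66	103	67
26	24	44
22	101	45
72	18	73
33	43	34
53	55	31
21	57	48
50	58	34
40	76	29
53	27	27
56	39	60
48	37	43
17	37	43
54	25	15
62	32	52
79	48	54
28	67	78
30	22	53
20	32	41
45	52	58
21	81	71
18	49	35
23	19	31
27	60	57
72	150	73
11	27	57
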