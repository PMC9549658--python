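rank	A	B	n_homozygotes	observed_frequency	expected_frequency
1	03	35	195	0.00940	0.009106
2	03	07	135	0.00651	0.005687
3	02	15	107	0.00516	0.005127
4	01	08	62	0.00299	0.003129
5	02	27	54	0.00260	0.002584
6	02	44	26	0.00125	0.000954
7	02	07	22	0.00106	0.001288
8	02	40	22	0.00106	0.001146
9	03	15	22	0.00106	0.000803
10	02	51	12	0.00058	0.000507
11	24	40	11	0.00053	0.000526
12	02	13	7	0.00034	0.000595
13	24	39	6	0.00029	0.000217
14	02	56	5	0.00024	0.000180
15	24	07	5	0.00024	0.000161
16	31	18	3	0.00014	0.000166
17	03	18	3	0.00014	0.000149
18	02	08	3	0.00014	0.000097
19	11	35	2	0.00010	0.000112
20	11	44	2	0.00010	0.000091
21	68	51	2	0.00010	0.000058
22	31	51	2	0.00010	0.000043
23	32	40	2	0.00010	0.000043
24	68	35	2	0.00010	0.000036
25	68	44	2	0.00010	0.000038
26	26	40	2	0.00010	0.000021
27	69	08	2	0.00010	0.000082
28	02	35	1	0.00005	0.000191
29	24	15	1	0.00005	0.000122
30	02	18	1	0.00005	0.000107
31	24	35	1	0.00005	0.000104
32	25	18	1	0.00005	0.000081
33	03	27	1	0.00005	0.000086
34	03	44	1	0.00005	0.000056
35	32	44	1	0.00005	0.000044
36	03	40	1	0.00005	0.000047
37	03	51	1	0.00005	0.000042
38	31	40	1	0.00005	0.000020
39	31	39	1	0.00005	0.000014
40	11	55	1	0.00005	0.000008
41	01	07	1	0.00005	0.000009
42	29	44	1	0.00005	0.000007
43	32	35	1	0.00005	0.000007
44	23	44	1	0.00005	0.000007
45	01	39	1	0.00005	0.000004
46	01	51	1	0.00005	0.000006
47	24	51	1	0.00005	0.000007
48	68	15	1	0.00005	0.000005
49	24	08	1	0.00005	0.000002
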