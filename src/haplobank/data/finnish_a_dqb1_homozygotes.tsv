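rank	A	B	C	DRB1	DQA1	DQB1	n_homozygotes	observed_frequency	expected_frequency	het_pct	fer	confirmed
1	03:01	35:01	04:01	01:01	01:01	05:01	149	0.00718522	0.00690815	0.12	0	0
2	01:01	08:01	07:01	03:01	05:01	02:01	48	0.00231470	0.00242061	0.41	0	0
3	03:01	07:02	07:02	15:01	01:02	06:02	27	0.00130202	0.00113331	0.64	0	0
4	02:01	07:02	07:02	15:01	01:02	06:02	7	0.00033756	0.00051551	2.11	0	1
5	02:01	13:02	06:02	07:01	02:01	02:02	7	0.00033756	0.00039721	0.67	0	1
6	02:01	15:01	03:04	04:01	03:01	03:02	7	0.00033756	0.00029789	1.23	0	1
7	03:01	07:02	07:02	13:01	01:03	06:03	6	0.00028934	0.00035215	1.62	0	0
8	02:01	27:05	02:02	08:01	04:01	04:02	5	0.00024111	0.00031656	0.01	0	0
9	02:01	51:01	15:02	09:01	03:02	03:03	5	0.00024111	0.00013848	0.02	1	1
10	03:01	15:01	03:03	08:01	04:01	04:02	5	0.00024111	0.00007897	0.02	1	0
11	02:01	15:01	03:03	13:01	01:03	06:03	4	0.00019289	0.00017316	2.31	0	0
12	24:02	40:01	03:04	13:02	01:02	06:04	4	0.00019289	0.00011964	0.12	0	0
13	02:01	27:05	01:02	01:01	01:01	05:01	4	0.00019289	0.00011769	1.16	0	0
14	02:01	15:01	04:01	08:01	04:01	04:02	3	0.00014467	0.00018545	0.09	0	0
15	03:01	18:01	07:01	04:04	03:01	03:02	3	0.00014467	0.00007943	0.02	1	1
16	02:01	08:01	07:01	03:01	05:01	02:01	3	0.00014467	0.00006399	2.21	0	0
17	31:01	18:01	07:01	15:01	01:02	06:02	2	0.00009645	0.00013433	0.03	1	0
18	03:01	07:02	03:04	01:01	01:01	05:01	2	0.00009645	0.00008789	2.43	1	0
19	02:01	40:01	03:04	13:02	01:02	06:04	2	0.00009645	0.00007268	2.35	0	0
20	24:02	39:01	07:02	08:01	04:01	04:02	2	0.00009645	0.00002717	2.90	1	0
21	02:01	15:01	04:01	15:01	01:02	06:02	2	0.00009645	0.00000850	0.40	1	0
22	02:01	44:02	05:01	12:01	05:05	03:01	1	0.00004822	0.00007523	5.20	0	0
23	68:01	08:01	07:01	03:01	05:01	02:01	1	0.00004822	0.00006170	0.00	0	0
24	02:01	27:05	01:02	04:08	03:03	03:01	1	0.00004822	0.00003359	0.03	1	0
25	24:02	35:01	04:01	01:01	01:01	05:01	1	0.00004822	0.00002598	0.02	0	0
26	02:01	56:01	01:02	04:01	03:01	03:02	1	0.00004822	0.00002582	0.01	1	0
27	03:01	15:01	03:04	04:01	03:01	03:02	1	0.00004822	0.00002199	0.06	0	0
28	31:01	51:01	01:02	13:01	03:02	03:03	1	0.00004822	0.00002156	0.40	1	1
29	02:01	56:01	01:02	15:01	01:02	06:02	1	0.00004822	0.00001116	0.03	1	0
30	02:01	27:05	02:02	01:01	01:01	05:01	1	0.00004822	0.00000611	6.73	0	0
31	29:02	44:03	16:01	07:01	02:01	02:02	1	0.00004822	0.00000374	0.08	0	0
32	23:01	44:03	04:01	07:01	02:01	02:02	1	0.00004822	0.00000318	0.25	0	0
33	32:01	40:02	03:04	14:02	05:03	03:01	1	0.00004822	0.00000300	0.14	0	0
34	03:01	15:01	03:03	13:02	01:02	06:04	1	0.00004822	0.00000290	0.01	0	0
35	32:01	35:01	04:01	04:01	03	03:01	1	0.00004822	0.00000218	0.07	0	0
36	11:01	44:02	05:01	04:04	03:01	03:02	1	0.00004822	0.00000146	0.03	0	0
37	32:01	44:02	05:01	15:01	01:02	06:02	1	0.00004822	0.00000127	0.06	0	0
38	11:01	35:01	03:03	08:01	04:01	04:02	1	0.00004822	0.00000048	0.06	0	0
39	25:01	08:01	07:01	03:01	05:01	02:01	1	0.00004822	0.00000008	0.08	0	0
40	26:01	40:02	03:04	08:01	04:01	04:02	1	0.00004822	0.00000004	0.12	0	0
41	02:01	51:01	15:02	04:01	03:01	03:02	1	0.00004822	0.00000001	0.03	0	0
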