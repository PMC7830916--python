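channel_id	source_id	detector_id	x	y	z	region	hemisphere
1	1	1	-50.8	-52.0	23.3	TPJ	left
2	2	2	-51.4	-55.9	22.9	TPJ	left
3	3	3	-43.7	36.4	33.3	MFG	left
4	4	4	-21.5	34.8	44.2	SFG	left
5	5	5	-10.4	53.6	44.2	SMFG	left
6	6	6	8.2	48.1	40.3	SMFG	right
7	7	7	22.6	40.5	36.5	SFG	right
8	8	8	40.8	39.9	30.5	MFG	right
9	9	9	53.8	-50.2	31.7	TPJ	right
10	10	10	49.5	-48.6	20.1	TPJ	right
11	11	11	-50.5	-53.2	27.7	TPJ	left
12	12	12	-42.7	35.2	31.0	MFG	left
13	13	13	-20.4	45.8	46.5	SFG	left
14	14	14	-7.3	46.3	38.4	SMFG	left
15	15	15	10.5	45.3	41.9	SMFG	right
16	1	16	18.8	45.8	40.9	SFG	right
17	2	1	19.9	36.4	39.2	SFG	right
18	3	2	39.0	28.8	24.1	MFG	right
19	4	3	51.3	-50.1	31.7	TPJ	right
20	5	4	49.0	-47.9	30.7	TPJ	right
21	6	5	-56.2	-25.3	-1.8	STG	left
22	7	6	-54.3	-16.4	9.4	STG	left
23	8	7	-52.2	25.0	12.9	IFG	left
24	9	8	-42.9	34.8	25.0	MFG	left
25	10	9	-24.7	36.2	38.3	SFG	left
26	11	10	-11.7	51.2	35.3	SMFG	left
27	12	11	5.1	42.7	45.9	SMFG	right
28	13	12	25.5	41.1	40.4	SFG	right
29	14	13	39.9	30.0	26.7	MFG	right
30	15	14	56.7	-27.9	7.5	STG	right
31	1	15	-50.9	-49.6	24.0	TPJ	left
32	2	16	-56.0	-21.5	-0.8	STG	left
33	3	1	-51.8	24.7	11.0	IFG	left
34	4	2	-44.1	37.1	27.2	MFG	left
35	5	3	-11.1	45.4	39.7	SMFG	left
36	6	4	20.1	43.4	41.2	SFG	right
37	7	5	40.7	29.2	36.0	MFG	right
38	8	6	51.8	28.6	3.8	IFG	right
39	9	7	61.4	-18.9	1.0	STG	right
40	10	8	60.0	-18.4	3.8	STG	right
41	11	9	-55.9	-24.3	4.5	STG	left
42	12	10	-53.4	31.5	10.9	IFG	left
43	13	11	-50.7	27.9	13.7	IFG	left
44	14	12	-8.7	53.8	42.5	SMFG	left
45	15	13	53.5	29.9	4.3	IFG	right
46	1	14	46.2	30.1	11.5	IFG	right
47	2	15	51.9	31.1	9.4	IFG	right
48	3	16	58.5	-25.6	2.5	STG	right
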