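source	FDM_x	BEM_x	SPH_x	FDM_y	BEM_y	SPH_y	FDM_z	BEM_z	SPH_z	FDM_RMS	BEM_RMS	SPH_RMS
1	0.76	0.74	0.82	0.74	0.76	0.83	0.65	0.75	0.71	0.71	0.75	0.79
2	0.66	0.67	0.75	0.61	0.64	0.78	0.52	0.77	0.65	0.58	0.70	0.73
3	0.57	0.66	0.69	0.55	0.57	0.46	0.46	0.80	0.49	0.48	0.69	0.56
4	0.51	0.61	0.46	0.55	0.56	0.44	0.52	0.78	0.35	0.47	0.66	0.42
5	0.67	0.71	0.77	0.64	0.71	0.8	0.55	0.80	0.65	0.60	0.74	0.74
6	0.75	0.74	0.8	0.74	0.74	0.82	0.64	0.77	0.7	0.70	0.75	0.78
7	0.6	0.57	0.66	0.58	0.63	0.62	0.52	0.69	0.44	0.56	0.64	0.58
8	0.61	0.56	0.74	0.55	0.62	0.68	0.56	0.70	0.53	0.57	0.63	0.66
9	0.7	0.73	0.8	0.65	0.65	0.81	0.61	0.78	0.68	0.64	0.72	0.77
10	0.72	0.71	0.81	0.66	0.69	0.81	0.59	0.81	0.7	0.64	0.74	0.78
11	0.77	0.75	0.8	0.75	0.76	0.83	0.65	0.79	0.69	0.71	0.77	0.78
12	0.76	0.73	0.79	0.72	0.74	0.81	0.6	0.81	0.66	0.70	0.76	0.76
13	0.74	0.72	0.83	0.69	0.72	0.83	0.66	0.81	0.73	0.69	0.75	0.80
14	0.75	0.69	0.83	0.7	0.72	0.83	0.66	0.78	0.73	0.69	0.74	0.80
15	0.76	0.72	0.82	0.73	0.74	0.84	0.66	0.78	0.72	0.70	0.75	0.80
16	0.76	0.76	0.83	0.74	0.77	0.85	0.66	0.83	0.73	0.70	0.79	0.81
17	0.63	0.72	0.77	0.7	0.54	0.83	0.47	0.81	0.63	0.58	0.70	0.75
18	0.68	0.74	0.78	0.7	0.57	0.83	0.53	0.81	0.67	0.62	0.72	0.76
19	0.74	0.74	0.82	0.73	0.75	0.83	0.66	0.82	0.71	0.70	0.77	0.79
20	0.74	0.75	0.8	0.72	0.71	0.82	0.64	0.74	0.68	0.69	0.73	0.77
21	0.72	0.68	0.8	0.65	0.70	0.82	0.63	0.80	0.68	0.65	0.73	0.77
22	0.72	0.72	0.82	0.68	0.70	0.83	0.63	0.80	0.69	0.66	0.75	0.79
23	0.75	0.72	0.83	0.71	0.74	0.84	0.65	0.79	0.74	0.68	0.76	0.80
24	0.73	0.66	0.82	0.73	0.74	0.83	0.63	0.77	0.73	0.68	0.73	0.80
25	0.64	0.70	0.77	0.64	0.64	0.76	0.57	0.70	0.62	0.59	0.68	0.73
26	0.6	0.64	0.72	0.59	0.65	0.64	0.52	0.77	0.55	0.55	0.69	0.64
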