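source	FDM_x	BEM_x	SPH_x	FDM_y	BEM_y	SPH_y	FDM_z	BEM_z	SPH_z	FDM_RMS	BEM_RMS	SPH_RMS
1	66.3	57.7	75.7	55	73.7	80	73.1	61.8	71.6	72.23	61.38	68.81
2	68.2	54.1	81.1	59	76.8	82.4	61.2	81.1	80.2	62.20	54.62	80.19
3	65	97.6	97.6	77.2	70.3	54.8	92.5	114.4	73.9	69.90	100.41	66.67
4	60.1	87.5	41.9	81.5	72.1	40.4	105.7	109.3	54.5	72.49	78.09	46.02
5	63	77.5	78.4	58.7	77.6	79.4	57.3	83.0	73.8	57.89	78.81	77.27
6	70.4	59.9	70.3	59.5	78.7	69.9	61.6	54.1	73.3	65.92	62.26	67.84
7	67.4	57.4	71.3	75.4	91.5	79.6	60.3	63.6	63.4	69.29	65.59	68.98
8	68.5	61.9	95.3	68.8	90.5	85.8	66.7	60.0	86.2	84.33	63.71	77.90
9	71.8	89.0	77.7	83.2	85.3	99.6	64.1	76.8	87.2	85.64	71.69	80.72
10	68.3	86.6	80.7	72.5	84.0	96.1	67.5	90.3	80.1	83.16	73.22	82.23
11	70.5	71.4	64.5	75.2	78.5	88.5	66.9	82.4	75.7	77.09	69.65	69.81
12	65	79.6	68.6	75.3	79.3	91.3	61.8	60.9	76.8	77.88	71.24	66.83
13	72.2	49.6	90.6	66.9	76.0	100.4	63.2	90.3	86.9	68.47	86.60	94.13
14	74.1	58.9	89.5	66.1	83.2	99.0	68.3	59.4	85.6	81.90	61.44	91.65
15	72.1	58.4	82.5	63	78.3	87.1	70.5	63.1	77.8	78.16	61.56	81.94
16	67.8	62.0	76.5	60.2	78.4	77.5	58.1	77.6	73.2	75.18	63.60	76.06
17	50.9	89.3	78.9	62.7	33.7	68.5	63	84.0	74.2	51.55	82.72	67.74
18	60.2	74.4	75.1	58.4	70.1	79.3	58.2	77.6	73.7	56.99	74.41	75.06
19	58.3	67.2	79.4	70.3	75.9	82.1	60.4	78.8	74.3	63.52	77.17	78.88
20	64.6	78.8	80	71.2	77.1	81.6	65.8	78.5	76.2	76.17	72.64	79.15
21	73.7	64.0	89.7	64.1	86.2	98.7	68.7	89.9	83.4	68.56	60.98	88.92
22	71.8	52.5	87.6	66.8	85.6	95.2	58.4	87.7	82	67.03	85.39	87.55
23	71.1	58.8	85.6	65.9	80.1	95.6	69.6	86.1	84	79.21	63.48	89.28
24	69.2	79.1	88.2	71.4	81.9	98.3	66.1	58.2	84.6	69.02	63.07	88.12
25	69.1	92.1	96.3	79.5	66.8	81.5	71.2	69.4	81	69.41	73.55	93.01
26	62.0	79.0	89.3	68.1	66.1	63.7	60.4	97.2	76.5	61.55	76.10	73.57
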