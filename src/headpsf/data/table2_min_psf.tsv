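source	FDM_x	BEM_x	SPH_x	FDM_y	BEM_y	SPH_y	FDM_z	BEM_z	SPH_z	FDM_RMS	BEM_RMS	SPH_RMS
1	0.4	0.12	0.42	0.38	0.13	0.28	-0.16	0.10	0.2	0.34	0.38	0.32
2	0.26	0.06	0.3	0.23	-0.03	0.29	0	0.06	0.17	0.25	0.33	0.27
3	0.23	-0.03	0.31	0.11	-0.33	0.06	-0.24	-0.22	-0.07	0.15	0.37	0.18
4	0.21	0.10	0.23	0.11	-0.17	0.08	-0.26	-0.38	-0.11	0.16	0.37	0.16
5	0.27	-0.24	0.3	0.23	0.11	0.16	-0.26	-0.21	0.14	0.27	0.44	0.27
6	0.37	0.09	0.39	0.37	0.06	0.24	-0.28	-0.03	0.18	0.36	0.33	0.30
7	0.23	-0.08	0.24	0.17	-0.21	-0.02	-0.12	-0.10	-0.11	0.21	0.25	0.15
8	0.23	0.08	0.28	0.14	-0.15	0.06	-0.14	-0.06	-0.07	0.23	0.22	0.17
9	0.32	-0.06	0.42	0.09	-0.21	0.38	0.02	-0.09	0.09	0.28	0.38	0.33
10	0.36	0.16	0.43	0.11	0.10	0.38	-0.22	-0.20	0.13	0.25	0.40	0.34
11	0.38	0.08	0.46	0.32	0.08	0.39	-0.09	0.07	0.14	0.31	0.43	0.37
12	0.44	0.12	0.44	0.26	0.14	0.38	-0.32	-0.06	0.13	0.28	0.37	0.35
13	0.31	-0.09	0.37	0.23	-0.15	0.22	-0.16	-0.10	0.13	0.29	0.32	0.27
14	0.33	0.12	0.38	0.23	-0.05	0.23	-0.06	0.05	0.15	0.31	0.30	0.27
15	0.35	0.12	0.39	0.31	0.10	0.26	-0.01	0.10	0.19	0.34	0.37	0.30
16	0.38	-0.03	0.38	0.33	0.00	0.26	-0.4	-0.11	0.19	0.36	0.37	0.31
17	0.31	0.06	0.32	0.27	-0.14	0.28	-0.11	-0.31	0.18	0.31	0.42	0.29
18	0.32	-0.08	0.34	0.33	-0.32	0.3	-0.02	-0.03	0.22	0.28	0.41	0.30
19	0.4	0.11	0.39	0.31	0.17	0.36	-0.28	-0.11	0.18	0.33	0.39	0.34
20	0.34	0.02	0.4	0.29	-0.03	0.36	0.02	0.11	0.14	0.32	0.37	0.35
21	0.29	0.14	0.34	0.08	-0.09	0.28	-0.06	-0.05	0.13	0.29	0.28	0.27
22	0.3	-0.23	0.35	0.15	-0.26	0.19	-0.08	-0.21	0.12	0.28	0.37	0.28
23	0.39	0.06	0.39	0.23	-0.07	0.22	-0.26	-0.04	0.16	0.34	0.29	0.27
24	0.34	0.20	0.39	0.32	-0.02	0.18	-0.17	0.04	0.15	0.33	0.25	0.26
25	0.24	-0.12	0.39	0.11	-0.18	0.34	-0.01	-0.40	0.05	0.25	0.35	0.30
26	0.27	0.17	0.35	-0.05	0.14	0.23	-0.33	-0.31	0	0.21	0.37	0.24
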