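region	a_pct	t_pct	g_pct	c_pct	at_pct	at_skew	gc_skew	length
Mitogenome	37.78	36.51	9.7	16.01	74.29	0.017	-0.246	15344
PCGs	29.72	42.98	13.79	13.51	72.70	-0.182	0.011	11077
cox1	29.29	38.55	15.46	16.70	67.84	-0.137	-0.039	1533
cox2	34.26	36.35	12.12	17.37	70.51	-0.031	-0.178	685
atp8	41.51	42.77	6.92	8.81	84.28	-0.015	-0.120	159
atp6	30.96	41.63	11.26	16.15	72.59	-0.147	-0.178	675
cox3	31.19	38.26	13.51	17.05	69.44	-0.102	-0.116	792
nad3	31.34	45.3	10.26	13.11	76.64	-0.280	0.341	351
nad5	28.51	46.90	15.60	8.99	75.42	-0.244	0.269	1680
nad4	26.10	48.32	17.30	8.28	74.42	-0.299	0.353	1341
nad4l	25.89	49.29	19.15	5.67	75.18	-0.311	0.543	282
nad6	31.98	44.19	7.17	16.67	76.16	-0.160	-0.398	516
cob	31.22	37.55	12.40	18.82	68.78	-0.092	-0.206	1137
nad1	26.02	46.24	18.60	9.14	72.26	-0.280	0.341	930
nad2	31.43	45.18	7.93	15.46	76.61	-0.180	-0.322	996
tRNAs	40.15	36.83	12.80	10.22	76.98	0.025	0.374	1477
rRNAs	39.83	37.90	15.30	6.97	77.73	-0.182	0.011	2079
AT-rich	31.62	42.16	8.92	17.30	77.78	-0.143	-0.320	371
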