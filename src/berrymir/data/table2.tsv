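mirna	bf_norm	wf_norm	fold_change	log2_fc	p_value	label	direction
vco-miR156c-3p	9.16	0.00	inf	inf	1.29e-5	**	up
vco-miR156f	10.82	0.00	inf	inf	1.06e-6	**	up
vco-miR159a	3.75	0.00	inf	inf	6.72e-3	**	up
vco-miR160a-5p	7.49	0.00	inf	inf	1.58e-4	**	up
vco-miR171a-3p	39.12	0.00	inf	inf	6.54e-22	**	up
vco-miR171a-5p	7.49	0.00	inf	inf	1.58e-4	**	up
vco-miR171b	6.66	0.00	inf	inf	1.58e-4	**	up
vco-miR394a-5p	87.40	0.00	inf	inf	5.47e-48	**	up
vco-miR398a-3p	4.16	0.00	inf	inf	6.72e-3	**	up
vco-miR398b-3p	4.16	0.00	inf	inf	6.72e-3	**	up
vco-miR398b-5p	11.24	0.00	inf	inf	1.06e-6	**	up
vco-miR166b-5p	77.42	1.20	64.44	6.01	8.31e-41	**	up
vco-miR319b	262.63	15.62	16.82	4.07	2.33e-120	**	up
vco-miR7693-5p	8.32	0.60	13.86	3.79	3.03e-4	**	up
vco-miR172a-5p	64.10	7.21	8.89	3.15	2.25e-27	**	up
vco-miR396e-5p	124.45	16.22	7.67	2.94	8.80e-50	**	up
vco-miR396f-5p	124.45	16.22	7.67	2.94	8.80e-50	**	up
vco-miR319a	365.02	49.85	7.32	2.87	2.54e-141	**	up
vco-miR319c	365.02	49.85	7.32	2.87	2.54e-141	**	up
vco-miR172a-3p	8.32	1.20	6.93	2.79	3.03e-4	**	up
vco-miR156h-3p	23.31	3.60	6.47	2.69	1.57e-9	**	up
vco-miR396c-5p	165.24	34.24	4.83	2.27	6.37e-57	**	up
vco-miR396d-5p	165.24	34.24	4.83	2.27	6.37e-57	**	up
vco-miR2603	4.58	1.20	3.81	1.93	8.79e-3	**	up
vco-miR396b-5p	69.51	22.82	3.05	1.61	1.73e-20	**	up
vco-miR398c-5p	69.09	22.82	3.03	1.60	4.57e-20	**	up
vco-miR166a	89.49	30.03	2.98	1.58	2.66e-25	**	up
vco-miR396a-5p	432.86	151.97	2.85	1.51	3.86e-114	**	up
vco-miR396d-3p	26.64	9.61	2.77	1.47	3.00e-8	**	up
vco-miR403a	89.90	34.84	2.58	1.37	1.39e-23	**	up
vco-miR390a-3p	4.58	1.80	2.54	1.35	2.35e-2	*	up
vco-miR390b-3p	4.58	1.80	2.54	1.35	2.35e-2	*	up
vco-miR6149a	14.15	6.01	2.36	1.24	1.51e-4	**	up
vco-miR166e-3p	159.83	72.08	2.22	1.15	5.95e-37	**	up
vco-miR_n11	116.12	21.02	5.52	2.47	2.51e-42	**	up
vco-miR_n07	69.92	16.82	4.16	2.06	1.67e-23	**	up
vco-miR_n14	19.15	4.81	3.98	1.99	4.17e-7	**	up
vco-miR_n10	350.45	97.31	3.60	1.85	6.93e-105	**	up
vco-miR_n06	21.23	10.21	2.08	1.06	7.25e-6	**	up
vco-miR894	340.46	1055.95	0.32	-1.63	3.70e-4	**	down
vco-miR_n12-3p	11.65	58.86	0.20	-2.34	3.46e-2	*	down
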