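label	nt_length	start	end	strand	aa_length	mass_kda	pi
TP84_01	567	13	579	+	188	22.4	7.76
TP84_02	1299	576	1874	+	432	50.0	7.74
TP84_03	687	1868	2554	+	228	26.3	9.17
TP84_04	354	2586	2939	+	117	13.6	4.36
TP84_05	198	2957	3154	+	65	7.5	4.63
TP84_06	1629	3174	4802	+	542	62.1	4.96
TP84_07	147	4799	4945	+	48	5.3	7.94
TP84_08	2046	4962	7007	+	681	78.0	8.71
TP84_09	210	7004	7213	+	69	8.2	4.89
TP84_10	828	7441	8268	+	275	31.6	4.70
TP84_11	408	8283	8690	+	135	14.0	5.84
TP84_12	993	8736	9728	+	330	37.8	4.98
TP84_13	195	9802	9996	+	64	7.2	9.19
TP84_14	330	10032	10361	+	109	12.2	5.16
TP84_15	324	10358	10681	+	107	11.9	6.26
TP84_16	489	10671	11159	+	162	18.7	6.26
TP84_17	378	11162	11539	+	125	14.6	5.35
TP84_18	558	11554	12111	+	185	20.3	4.38
TP84_19	507	12220	12726	+	168	19.3	4.90
TP84_20	375	12687	13061	+	124	14.7	9.80
TP84_21	2598	13081	15678	+	865	93.1	9.70
TP84_22	738	15684	16421	+	245	27.8	5.15
TP84_23	2634	16438	19071	+	877	99.3	5.06
TP84_24	210	19061	19270	+	69	7.9	4.59
TP84_25	900	19283	20182	+	299	34.5	5.35
TP84_26	2976	20179	23154	+	991	112.2	5.49
TP84_27	432	23240	23671	+	143	15.5	6.20
TP84_28	1185	23676	24860	+	394	44.2	9.67
TP84_29	201	24877	25077	+	66	7.2	8.03
TP84_30	573	25329	25901	+	190	21.7	4.98
TP84_31	156	26023	26178	+	51	6.0	6.15
TP84_32	255	26235	26489	+	84	9.8	9.70
TP84_33	291	26597	26887	+	96	11.0	5.10
TP84_34	255	26884	27138	+	84	9.6	4.48
TP84_35	207	27135	27341	+	68	7.9	11.60
TP84_36	237	27353	27589	+	78	9.3	9.91
TP84_37	396	27698	28093	+	131	14.9	6.41
TP84_38	201	28090	28290	+	66	7.4	6.73
TP84_39	216	28403	28618	+	71	8.1	7.96
TP84_40	210	28615	28824	+	69	8.2	9.39
TP84_41	273	28824	29096	+	90	10.6	9.69
TP84_42	162	29169	29330	+	53	6.4	5.71
TP84_43	309	29330	29639	+	102	11.0	9.81
TP84_44	132	29708	29839	+	43	5.0	10.62
TP84_45	231	29839	30069	+	76	8.5	9.75
TP84_46	213	30071	30283	+	70	7.8	10.01
TP84_47	381	30252	30632	+	126	13.8	7.85
TP84_48	2265	30527	32791	+	754	86.0	7.09
TP84_49	474	32871	33344	+	157	18.0	5.85
TP84_50	159	33468	33626	+	52	5.8	6.53
TP84_51	159	33832	33990	+	52	6.1	10.41
TP84_52	237	34030	34266	+	78	8.5	5.36
TP84_53	1017	34238	35254	+	338	38.5	5.33
TP84_54	1020	35270	36289	+	339	38.8	5.78
TP84_55	222	36337	36558	+	73	8.8	4.54
TP84_56	183	36924	37106	+	60	7.4	9.25
TP84_57	783	37127	37909	+	260	30.3	8.57
TP84_58	318	37942	38259	+	105	12.3	4.92
TP84_59	1305	38259	39563	+	434	49.1	5.53
TP84_60	672	39632	40303	+	223	26.4	8.41
TP84_61	435	40281	40715	+	144	16.7	9.08
TP84_62	147	40699	40845	+	48	5.9	9.10
TP84_63	468	40851	41318	+	155	17.4	5.16
TP84_64	240	41343	41582	+	79	9.3	6.89
TP84_65	150	41596	41745	+	49	5.5	8.10
TP84_66	270	41751	42020	+	89	10.4	5.92
TP84_67	183	42023	42205	+	60	6.9	4.58
TP84_68	987	42209	43195	+	328	38.6	6.91
TP84_69	501	43200	43700	+	166	20.0	5.67
TP84_70	330	43704	44033	+	109	12.7	9.47
TP84_71	246	44014	44259	+	81	9.4	10.21
TP84_72	504	44246	44749	+	167	19.3	7.70
TP84_73	264	44746	45009	+	87	10.4	5.60
TP84_74	546	44984	45529	+	181	21.4	9.19
TP84_75	114	45546	45659	+	37	4.0	3.76
TP84_76	126	45675	45800	+	41	4.8	5.54
TP84_77	186	45857	46042	+	61	7.2	9.19
TP84_78	204	46047	46250	+	67	7.5	12.16
TP84_79	354	46380	46733	+	117	13.4	7.82
TP84_80	366	46741	47106	+	121	14.0	6.82
TP84_81	141	47379	47519	+	46	5.3	9.59
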