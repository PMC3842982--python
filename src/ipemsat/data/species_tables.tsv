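sample	genus	library_prep	n_ssr_pairs	n_pal	ssr_6mer	ssr_5mer	ssr_4mer	ssr_3mer	ssr_2mer	n_ppal	ppal_6mer	ppal_5mer	ppal_4mer	ppal_3mer	ppal_2mer
1	Stictotarsus	nextera	50735	2576	1333	3413	6072	3946	35971	201	3	0	3	71	124
2	Megacopta	truseq	86717	13953	28	122	2408	6674	77485	2423	0	2	12	238	2171
3	Junonia	nextera	62927	6998	250	34241	1790	4599	6747	136	0	1	44	53	38
4	Mesocapnia	truseq	73137	13090	2462	11669	9277	14391	35338	937	2	39	68	180	648
5	Paralithodes	nextera	430868	54838	350	194790	20956	51573	163199	19407	16	51	913	3213	15214
6	Uca	nextera	644886	144502	70	13010	42400	199907	389499	52682	2	239	2368	12449	37624
7	Uca	truseq	545301	94805	114	13360	40449	88638	402740	24022	1	179	1061	5879	16902
8	Rhinichthys	truseq	238812	30099	2796	1560	106375	9013	119069	4635	3	21	188	439	3984
9	Prosopium	nextera	286604	26109	140	257	1943	3374	20395	6671	26	32	491	830	5292
10	Ambystoma	nextera	5970	1582	4	70	290	554	664	322	1	9	62	91	159
11	Eurycea	nextera	27272	4198	1572	1043	16853	4281	3523	1118	13	54	426	411	214
12	Alca	nextera	14288	2136	4189	2054	2246	1995	3804	667	11	51	165	287	148
13	Ptychoramphus	nextera	17166	3093	26	274	608	1444	741	1016	6	83	246	419	262
14	Campylorhynchus	truseq	113109	4760	64127	28928	11599	5837	2618	845	29	59	149	377	231
15	Pelecanus	nextera	12421	2554	2450	3459	1344	3032	2135	626	9	55	107	317	138
16	Sula	truseq	82003	3913	4275	69353	1684	4531	2160	949	20	69	119	442	299
17	Oceanodroma	nextera	2541	418	592	390	217	646	696	165	1	11	29	69	56
18	Tursiops	nextera	34387	6999	2150	301	4110	2411	25415	2150	2	8	261	297	1582
19	Ectophyla	truseq	25278	7403	2774	253	4344	3096	14811	3178	8	29	442	454	2246
20	Tlacuatzin	truseq	94285	12811	3865	2821	36927	13016	37656	7049	30	65	1062	1595	4297
21	Onychomys	truseq	132502	33500	86	316	4433	3817	24848	17797	39	120	1914	1695	14029
22	Lampropeltis	truseq	244857	26215	302	4144	8975	5967	6827	6314	48	474	1948	1563	2281
23	Sceloporus	truseq	139529	46255	4320	1092	21778	63513	48827	14511	10	107	2014	6509	5871
24	Batagur	truseq	22319	6370	19	71	486	1146	4648	2545	8	22	169	411	1935
25	Leptodea	nextera	105238	8601	4015	606	44611	13035	42971	1163	0	3	91	285	784
26	Canarina	truseq	37868	7242	8	12	60	1440	5722	2722	2	6	15	413	2286
27	Solidago	nextera	31634	7607	75	405	405	4555	2167	813	6	38	49	466	254
28	Echinocereus	nextera	60583	6964	58	539	1159	2597	2611	1208	9	97	94	422	586
29	Lupinus	nextera	391973	5845	105	2154	426	1841	1319	803	6	145	65	382	205
30	Bencomia	truseq	42786	14777	1295	723	606	14632	25530	402	8	6	10	97	281
31	Mimulus	truseq	32170	7232	400	147	484	7907	23232	791	3	2	5	195	586
32	Juniperus	truseq	21352	2853	18	36	87	1375	1337	1180	3	6	39	421	711
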