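site_id	d6_pos_grch37	d6_pos_grch38	d7_pos_grch37	d7_pos_grch38	d6_base	d7_base	segment
0	42522015	42126013	42535193	42139191	T	C	3p_flank
1	42522067	42126065	42535245	42139243	G	A	3p_flank
2	42522119	42126117	42535297	42139295	C	T	3p_flank
3	42522171	42126169	42535349	42139347	A	G	3p_flank
4	42522223	42126221	42535401	42139399	G	T	3p_flank
5	42522275	42126273	42535453	42139451	A	C	3p_flank
6	42522327	42126325	42535505	42139503	T	C	3p_flank
7	42522379	42126377	42535557	42139555	G	A	3p_flank
8	42522431	42126429	42535609	42139607	C	T	3p_flank
9	42522483	42126481	42535661	42139659	A	G	3p_flank
10	42522570	42126568	42535748	42139746	A	C	exon9
11	42522587	42126585	42535765	42139763	T	C	exon9
12	42522603	42126601	42535781	42139779	G	A	exon9
13	42522619	42126617	42535797	42139795	C	T	exon9
14	42522634	42126632	42535812	42139810	A	G	exon9
15	42522651	42126649	42535829	42139827	G	T	exon9
16	42522667	42126665	42535845	42139843	A	C	exon9
17	42522683	42126681	42535861	42139859	T	C	exon9
18	42522699	42126697	42535877	42139875	G	A	exon9
19	42522715	42126713	42535893	42139891	C	T	exon9
20	42522731	42126729	42535909	42139907	A	G	exon9
21	42522747	42126745	42535925	42139923	G	T	exon9
22	42522763	42126761	42535941	42139939	A	C	exon9
23	42522923	42126921	42536101	42140099	T	C	exon8
24	42522937	42126935	42536115	42140113	G	A	exon8
25	42522951	42126949	42536129	42140127	C	T	exon8
26	42522965	42126963	42536143	42140141	A	G	exon8
27	42522979	42126977	42536157	42140155	G	T	exon8
28	42522993	42126991	42536171	42140169	A	C	exon8
29	42523007	42127005	42536185	42140183	T	C	exon8
30	42523021	42127019	42536199	42140197	G	A	exon8
31	42523035	42127033	42536213	42140211	C	T	exon8
32	42523049	42127047	42536227	42140225	A	G	exon8
33	42523063	42127061	42536241	42140239	G	T	exon8
34	42523409	42127407	42536587	42140585	T	C	exon7
35	42523423	42127421	42536601	42140599	G	A	exon7
36	42523437	42127435	42536615	42140613	C	T	exon7
37	42523451	42127449	42536629	42140627	A	G	exon7
38	42523465	42127463	42536643	42140641	G	T	exon7
39	42523479	42127477	42536657	42140655	A	C	exon7
40	42523493	42127491	42536671	42140669	T	C	exon7
41	42523507	42127505	42536685	42140683	G	A	exon7
42	42523521	42127519	42536699	42140697	C	T	exon7
43	42523535	42127533	42536713	42140711	A	G	exon7
44	42523549	42127547	42536727	42140725	G	T	exon7
45	42523563	42127561	42536741	42140739	A	C	exon7
46	42523883	42127881	42537061	42141059	G	A	exon6
47	42523901	42127899	42537079	42141077	C	T	exon6
48	42523919	42127917	42537097	42141095	A	G	exon6
49	42523937	42127935	42537115	42141113	G	T	exon6
50	42523955	42127953	42537133	42141131	A	C	exon6
51	42523973	42127971	42537151	42141149	T	C	exon6
52	42523991	42127989	42537169	42141167	G	A	exon6
53	42524009	42128007	42537187	42141185	C	T	exon6
54	42524027	42128025	42537205	42141203	A	G	exon6
55	42524045	42128043	42537223	42141221	G	T	exon6
56	42524063	42128061	42537241	42141239	A	C	exon6
57	42524195	42128193	42537373	42141371	A	G	exon5
58	42524219	42128217	42537397	42141395	G	T	exon5
59	42524237	42128235	42537415	42141413	A	C	exon5
60	42524255	42128253	42537433	42141431	T	C	exon5
61	42524273	42128271	42537451	42141449	G	A	exon5
62	42524291	42128289	42537469	42141467	C	T	exon5
63	42524309	42128307	42537487	42141485	A	G	exon5
64	42524327	42128325	42537505	42141503	G	T	exon5
65	42524345	42128343	42537523	42141521	A	C	exon5
66	42524363	42128361	42537541	42141539	T	C	exon5
67	42524803	42128801	42537981	42141979	A	C	exon4
68	42524823	42128821	42538001	42141999	T	C	exon4
69	42524843	42128841	42538021	42142019	G	A	exon4
70	42524863	42128861	42538041	42142039	C	T	exon4
71	42524883	42128881	42538061	42142059	A	G	exon4
72	42524903	42128901	42538081	42142079	G	T	exon4
73	42524923	42128921	42538101	42142099	A	C	exon4
74	42524943	42128941	42538121	42142119	T	C	exon4
75	42524963	42128961	42538141	42142139	G	A	exon4
76	42524983	42128981	42538161	42142159	C	T	exon4
77	42525033	42129031	42538211	42142209	G	A	exon3
78	42525053	42129051	42538231	42142229	C	T	exon3
79	42525073	42129071	42538251	42142249	A	G	exon3
80	42525093	42129091	42538271	42142269	G	T	exon3
81	42525113	42129111	42538291	42142289	A	C	exon3
82	42525133	42129131	42538311	42142309	T	C	exon3
83	42525153	42129151	42538331	42142329	G	A	exon3
84	42525173	42129171	42538351	42142349	C	T	exon3
85	42525193	42129191	42538371	42142369	A	G	exon3
86	42525213	42129211	42538391	42142389	G	T	exon3
87	42525701	42129699	42538879	42142877	A	G	exon2
88	42525719	42129717	42538897	42142895	G	T	exon2
89	42525737	42129735	42538915	42142913	A	C	exon2
90	42525755	42129753	42538933	42142931	T	C	exon2
91	42525773	42129771	42538951	42142949	G	A	exon2
92	42525790	42129788	42538968	42142966	C	T	exon2
93	42525809	42129807	42538987	42142985	A	G	exon2
94	42525827	42129825	42539005	42143003	G	T	exon2
95	42525845	42129843	42539023	42143021	A	C	exon2
96	42525863	42129861	42539041	42143039	T	C	exon2
97	42526493	42130491	42539671	42143669	A	G	exon1
98	42526522	42130520	42539700	42143698	G	T	exon1
99	42526551	42130549	42539729	42143727	A	C	exon1
100	42526580	42130578	42539758	42143756	T	C	exon1
101	42526609	42130607	42539787	42143785	G	A	exon1
102	42526638	42130636	42539816	42143814	C	T	exon1
103	42526667	42130665	42539845	42143843	A	G	exon1
104	42526696	42130694	42539874	42143872	G	T	exon1
105	42526725	42130723	42539903	42143901	A	C	exon1
106	42526754	42130752	42539932	42143930	T	C	exon1
107	42526783	42130781	42539961	42143959	G	A	exon1
108	42526812	42130810	42539990	42143988	C	T	exon1
109	42526826	42130824	42540004	42144002	G	A	5p_flank
110	42526867	42130865	42540045	42144043	C	T	5p_flank
111	42526908	42130906	42540086	42144084	A	G	5p_flank
112	42526949	42130947	42540127	42144125	G	T	5p_flank
113	42526990	42130988	42540168	42144166	A	C	5p_flank
114	42527031	42131029	42540209	42144207	T	C	5p_flank
115	42527072	42131070	42540250	42144248	G	A	5p_flank
116	42527113	42131111	42540291	42144289	C	T	5p_flank
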