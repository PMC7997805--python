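g_label	g_pos	ref	alt	kind
g.7A>G	7	A	G	snv
g.19G>A	19	G	A	snv
g.31G>A	31	G	A	snv
g.77G>A	77	G	A	snv
g.82C>T	82	C	T	snv
g.100C>T	100	C	T	snv
g.125G>A	125	G	A	snv
g.137_138insT	137	-	T	ins
g.218G>A	218	G	A	snv
g.883G>C	883	G	C	snv
g.1022C>T	1022	C	T	snv
g.1612T>A	1612	T	A	snv
g.1659G>A	1659	G	A	snv
g.1708delT	1708	T	-	del
g.1716G>A	1716	G	A	snv
g.1757C>T	1757	C	T	snv
g.1758G>A	1758	G	A	snv
g.1847G>A	1847	G	A	snv
g.1863_1864insTTTCGCCCC	1863	-	TTTCGCCCC	ins
g.1869T>C	1869	T	C	snv
g.1897C>T	1897	C	T	snv
g.2129A>C	2129	A	C	snv
g.2312G>A	2312	G	A	snv
g.2483G>T	2483	G	T	snv
g.2549delA	2549	A	-	del
g.2573_2574insC	2573	-	C	ins
g.2615_2617delAAG	2615	AAG	-	del
g.2851C>T	2851	C	T	snv
g.2853A>C	2853	A	C	snv
g.2939G>A	2939	G	A	snv
g.2989G>A	2989	G	A	snv
g.3183G>A	3183	G	A	snv
g.3201C>T	3201	C	T	snv
g.3254T>C	3254	T	C	snv
g.3277T>C	3277	T	C	snv
g.3387C>T	3387	C	T	snv
g.3790C>T	3790	C	T	snv
g.4042G>A	4042	G	A	snv
g.4043G>A	4043	G	A	snv
g.4065G>A	4065	G	A	snv
g.4115C>T	4115	C	T	snv
g.4181G>C	4181	G	C	snv
g.4242G>A	4242	G	A	snv
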