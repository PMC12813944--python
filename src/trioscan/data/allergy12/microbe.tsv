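rsid	chrom	pos	effect_allele	pvalue	trait	study_id
rs687289	9	136137065	G	8.95E-14	Bifidobacterium bifidum	mgwas_kurilshikov2021
rs763101897	22	33100000	T	5.33E-07	Ruminococcus gnavus	mgwas_ruhlemann2021
rs367882553	5	110600000	G	5.94E-07	Dorea longicatena	mgwas_loperamaya2022
rs139280910	6	129400000	C	7.2E-09	Bifidobacterium angulatum	mgwas_qin2022
rs6072799	20	41000000	C	5.52E-07	Bifidobacterium angulatum	mgwas_kurilshikov2021
rs11371772	3	143100000	T	3.26E-07	Neisseria gonorrhoeae	mgwas_ruhlemann2021
rs552913575	4	183200000	C	7.73E-07	Granulicatella adiacens	mgwas_loperamaya2022
rs146139464	2	236600000	C	7.45E-07	Eggerthella lenta	mgwas_qin2022
rs61885278	11	24700000	G	3.5E-08	Prevotella buccae	mgwas_kurilshikov2021
rs1467463821	2	183100000	C	3.60E-07	Megasphaera micronuciformis	mgwas_ruhlemann2021
rs4683988	3	76500000	A	8.79E-07	Bacteroides clarus	mgwas_loperamaya2022
rs575866680	4	167800000	G	5.18E-08	Megasphaera micronuciformis	mgwas_qin2022
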