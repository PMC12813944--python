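rsid	chrom	pos	effect_allele	pvalue	trait	study_id
rs532436	9	136149399	T	7.69E-13	Campesterol	bgwas_shin2014
rs2008206	22	33150000	C	5.03E-06	Succinylcarnitine	bgwas_chen2023
rs6875225	5	110650000	G	9.08E-06	4-Cholesten-3-one	bgwas_surendran2022
rs265369	6	129450000	T	1.24E-07	Octadecanedioate	bgwas_yin2022
rs6030381	20	41050000	C	1.97E-07	Octanoylcarnitine	bgwas_shin2014
rs12488603	3	143150000	T	9.86E-06	N-oleoyltaurine	bgwas_chen2023
rs7694663	4	183250000	A	8.91E-06	Isoeugenol sulfate	bgwas_surendran2022
rs2675124	2	236650000	C	4.75E-06	3-Phenylpropionate	bgwas_yin2022
rs2716449	11	24750000	T	1.06E-06	Choline phosphate	bgwas_shin2014
rs1432523	2	183150000	G	2.61E-06	Lactosyl-N-behenoyl-sphingosine	bgwas_chen2023
rs2593865	3	76550000	A	2.32E-08	Glycosyl ceramide	bgwas_surendran2022
rs56258049	4	167850000	C	5.81E-06	N-acetyl-aspartyl-glutamate	bgwas_yin2022
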