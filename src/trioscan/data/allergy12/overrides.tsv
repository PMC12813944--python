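rsid	gene
rs687289	ABO
rs532436	ABO
rs763101897	SYN3
rs2008206	SYN3
rs367882553	CAMK4
rs6875225	CAMK4
rs139280910	LAMA2
rs265369	LAMA2
rs6072799	PTPRT
rs6030381	PTPRT
rs11371772	SLC9A9
rs12488603	SLC9A9
rs552913575	TENM3
rs7694663	TENM3
rs146139464	AGAP1
rs2675124	AGAP1
rs61885278	LUZP2
rs2716449	LUZP2
rs1467463821	PDE1A
rs1432523	PDE1A
rs4683988	ROBO2
rs2593865	ROBO2
rs575866680	SPOCK3
rs56258049	SPOCK3
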