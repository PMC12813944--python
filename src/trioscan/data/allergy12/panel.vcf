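##fileformat=VCFv4.2
##source=trioscan-example (stub panel: trio SNP pairs in perfect LD)
##contig=<ID=2>
##contig=<ID=3>
##contig=<ID=4>
##contig=<ID=5>
##contig=<ID=6>
##contig=<ID=9>
##contig=<ID=11>
##contig=<ID=20>
##contig=<ID=22>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	EX000	EX001	EX002	EX003
2	183100000	rs1467463821	G	C	.	PASS	.	GT	1|0	1|1	1|0	1|0
2	183150000	rs1432523	A	C	.	PASS	.	GT	1|0	1|1	1|0	1|0
2	236600000	rs146139464	C	G	.	PASS	.	GT	1|1	1|1	1|1	0|0
2	236650000	rs2675124	C	T	.	PASS	.	GT	1|1	1|1	1|1	0|0
3	76500000	rs4683988	C	T	.	PASS	.	GT	0|1	1|0	1|0	1|1
3	76550000	rs2593865	A	G	.	PASS	.	GT	0|1	1|0	1|0	1|1
3	143100000	rs11371772	G	C	.	PASS	.	GT	1|0	0|0	0|0	1|1
3	143150000	rs12488603	C	T	.	PASS	.	GT	1|0	0|0	0|0	1|1
4	167800000	rs575866680	G	T	.	PASS	.	GT	1|1	1|0	0|1	0|0
4	167850000	rs56258049	G	T	.	PASS	.	GT	1|1	1|0	0|1	0|0
4	183200000	rs552913575	T	G	.	PASS	.	GT	1|1	1|1	1|0	0|0
4	183250000	rs7694663	A	T	.	PASS	.	GT	1|1	1|1	1|0	0|0
5	110600000	rs367882553	C	G	.	PASS	.	GT	1|1	1|1	1|1	0|0
5	110650000	rs6875225	T	G	.	PASS	.	GT	1|1	1|1	1|1	0|0
6	129400000	rs139280910	G	T	.	PASS	.	GT	1|1	1|0	0|0	1|1
6	129450000	rs265369	T	C	.	PASS	.	GT	1|1	1|0	0|0	1|1
9	136137065	rs687289	C	T	.	PASS	.	GT	1|1	0|0	1|0	0|1
9	136149399	rs532436	A	G	.	PASS	.	GT	1|1	0|0	1|0	0|1
11	24700000	rs61885278	G	A	.	PASS	.	GT	1|0	0|1	0|0	1|0
11	24750000	rs2716449	C	T	.	PASS	.	GT	1|0	0|1	0|0	1|0
20	41000000	rs6072799	A	C	.	PASS	.	GT	1|0	0|0	1|0	0|1
20	41050000	rs6030381	C	A	.	PASS	.	GT	1|0	0|0	1|0	0|1
22	33100000	rs763101897	G	C	.	PASS	.	GT	0|1	0|1	0|0	1|0
22	33150000	rs2008206	G	T	.	PASS	.	GT	0|1	0|1	0|0	1|0
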