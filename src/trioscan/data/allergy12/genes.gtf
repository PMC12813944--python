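9	example	gene	136117065	136169399	.	+	.	gene_id "ABO"; gene_name "ABO"; gene_biotype "protein_coding";
22	example	gene	33080000	33170000	.	+	.	gene_id "SYN3"; gene_name "SYN3"; gene_biotype "protein_coding";
5	example	gene	110580000	110670000	.	+	.	gene_id "CAMK4"; gene_name "CAMK4"; gene_biotype "protein_coding";
6	example	gene	129380000	129470000	.	+	.	gene_id "LAMA2"; gene_name "LAMA2"; gene_biotype "protein_coding";
20	example	gene	40980000	41070000	.	+	.	gene_id "PTPRT"; gene_name "PTPRT"; gene_biotype "protein_coding";
3	example	gene	143080000	143170000	.	+	.	gene_id "SLC9A9"; gene_name "SLC9A9"; gene_biotype "protein_coding";
4	example	gene	183180000	183270000	.	+	.	gene_id "TENM3"; gene_name "TENM3"; gene_biotype "protein_coding";
2	example	gene	236580000	236670000	.	+	.	gene_id "AGAP1"; gene_name "AGAP1"; gene_biotype "protein_coding";
11	example	gene	24680000	24770000	.	+	.	gene_id "LUZP2"; gene_name "LUZP2"; gene_biotype "protein_coding";
2	example	gene	183080000	183170000	.	+	.	gene_id "PDE1A"; gene_name "PDE1A"; gene_biotype "protein_coding";
3	example	gene	76480000	76570000	.	+	.	gene_id "ROBO2"; gene_name "ROBO2"; gene_biotype "protein_coding";
4	example	gene	167780000	167870000	.	+	.	gene_id "SPOCK3"; gene_name "SPOCK3"; gene_biotype "protein_coding";
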