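entity	class	trait	provenance
ABO	gene	allergic diseases (asthma, rhinitis, and eczema)	gwas_catalog_like
CAMK4	gene	asthma	gwas_catalog_like
LAMA2	gene	asthma	gwas_catalog_like
PTPRT	gene	asthma	gwas_catalog_like
SLC9A9	gene	asthma	gwas_catalog_like
TENM3	gene	asthma	gwas_catalog_like
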