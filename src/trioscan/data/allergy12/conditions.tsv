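gene	condition
ABO	allergic diseases (asthma, rhinitis, and eczema)
SYN3	allergic diseases (asthma, rhinitis, and eczema)
CAMK4	asthma
LAMA2	asthma
PTPRT	asthma
SLC9A9	asthma
TENM3	asthma
AGAP1	eczema
LUZP2	eczema
PDE1A	eczema
ROBO2	eczema
SPOCK3	eczema
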