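entity	class	trait	provenance
Campesterol	metabolite	plant sterol biomarker	hmdb_like
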