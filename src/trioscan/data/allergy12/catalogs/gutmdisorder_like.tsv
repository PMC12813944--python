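entity	class	trait	provenance
Ruminococcus gnavus	microbe	allergic diseases (asthma, rhinitis, and eczema)	gutmdisorder_like
Eggerthella lenta	microbe	eczema	gutmdisorder_like
Prevotella buccae	microbe	eczema	gutmdisorder_like
Megasphaera micronuciformis	microbe	eczema	gutmdisorder_like
Bacteroides clarus	microbe	eczema	gutmdisorder_like
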