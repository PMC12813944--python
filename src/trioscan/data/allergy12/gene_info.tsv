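gene	function
ABO	Glycosphingolipid biosynthesis
SYN3	Neurotransmitter release and synaptic function
CAMK4	Calcium-dependent signaling
LAMA2	Tissue structure scaffolding
PTPRT	Regulates cellular processes including growth and differentiation
SLC9A9	A sodium/hydrogen exchanger/transporter
TENM3	Neuronal development, immune regulation, and inflammation
AGAP1	Intracellular trafficking, endocytosis
LUZP2	Cytoskeleton and cellular shape
PDE1A	Cellular signaling, regulating smooth muscle contraction
ROBO2	Axon guidance
SPOCK3	Regulating extracellular matrix and cell-matrix interactions
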