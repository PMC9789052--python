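label	gene
PhyloSET	GENE00001
PhyloSET	GENE00002
PhyloSET	GENE00005
PhyloSET	GENE00016
PhyloSET	GENE00018
PhyloSET	GENE00019
PhyloSET	GENE00020
PhyloSET	GENE00021
PhyloSET	GENE00023
PhyloSET	GENE00024
PhyloSET	GENE00029
PhyloSET	GENE00031
PhyloSET	GENE00032
PhyloSET	GENE00033
PhyloSET	GENE00038
PhyloSET	GENE00041
PhyloSET	GENE00042
PhyloSET	GENE00044
PhyloSET	GENE00049
PhyloSET	GENE00051
PhyloSET	GENE00052
PhyloSET	GENE00057
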