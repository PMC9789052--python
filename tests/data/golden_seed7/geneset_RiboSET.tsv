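label	gene
RiboSET	GENE00000
RiboSET	GENE00001
RiboSET	GENE00002
RiboSET	GENE00003
RiboSET	GENE00004
RiboSET	GENE00005
RiboSET	GENE00007
RiboSET	GENE00009
RiboSET	GENE00011
RiboSET	GENE00029
RiboSET	GENE00030
RiboSET	GENE00031
RiboSET	GENE00032
RiboSET	GENE00033
RiboSET	GENE00034
RiboSET	GENE00035
RiboSET	GENE00036
RiboSET	GENE00037
RiboSET	GENE00038
RiboSET	GENE00039
RiboSET	GENE00040
RiboSET	GENE00041
RiboSET	GENE00042
RiboSET	GENE00044
RiboSET	GENE00045
RiboSET	GENE00046
RiboSET	GENE00047
RiboSET	GENE00048
RiboSET	GENE00049
RiboSET	GENE00050
RiboSET	GENE00051
RiboSET	GENE00053
RiboSET	GENE00054
RiboSET	GENE00055
RiboSET	GENE00056
RiboSET	GENE00057
RiboSET	GENE00059
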