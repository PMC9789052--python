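label	gene
RiboSET_ext	GENE00000
RiboSET_ext	GENE00001
RiboSET_ext	GENE00002
RiboSET_ext	GENE00003
RiboSET_ext	GENE00004
RiboSET_ext	GENE00005
RiboSET_ext	GENE00007
RiboSET_ext	GENE00009
RiboSET_ext	GENE00011
RiboSET_ext	GENE00029
RiboSET_ext	GENE00030
RiboSET_ext	GENE00031
RiboSET_ext	GENE00032
RiboSET_ext	GENE00033
RiboSET_ext	GENE00034
RiboSET_ext	GENE00035
RiboSET_ext	GENE00036
RiboSET_ext	GENE00037
RiboSET_ext	GENE00038
RiboSET_ext	GENE00039
RiboSET_ext	GENE00040
RiboSET_ext	GENE00041
RiboSET_ext	GENE00042
RiboSET_ext	GENE00044
RiboSET_ext	GENE00045
RiboSET_ext	GENE00046
RiboSET_ext	GENE00047
RiboSET_ext	GENE00048
RiboSET_ext	GENE00049
RiboSET_ext	GENE00050
RiboSET_ext	GENE00051
RiboSET_ext	GENE00053
RiboSET_ext	GENE00054
RiboSET_ext	GENE00055
RiboSET_ext	GENE00056
RiboSET_ext	GENE00057
RiboSET_ext	GENE00059
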