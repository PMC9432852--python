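covariate,count
N. sibirica,33594
K. ceratoides,18555
K. cuspidatum,16999
A. splendens,2118
K. gracile,1106
R. soongarica,1053
S. physophora,460
K. foliatum,95
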