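label,sample_size,age_min,age_max,haplotype_diversity
NEE,621,0,0,0.98
saa,118,0,0,0.81
CE,1030,0,0,0.97
aHG,20,168,614,0.91
aUzPo,11,300,300,0.74
aBOO,23,140,140,0.82
aPWC,19,116,116,0.80
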