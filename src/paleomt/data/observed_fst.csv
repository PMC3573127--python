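pop_a,pop_b,fst
NEE,saa,0.1245
NEE,CE,0.0040
NEE,aHG,0.0765
NEE,aUzPo,0.0538
NEE,aBOO,0.1232
NEE,aPWC,0.0507
saa,aHG,0.1879
saa,aUzPo,0.1391
saa,aBOO,0.1698
saa,aPWC,0.1993
CE,aUzPo,0.6564
CE,aBOO,0.1418
aHG,aUzPo,0.1520
aHG,aBOO,0.1680
aHG,aPWC,0.0943
aUzPo,aBOO,0.0577
aUzPo,aPWC,0.0630
aBOO,aPWC,0.1723
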