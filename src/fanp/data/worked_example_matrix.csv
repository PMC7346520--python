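row,col,l,m,u
Efficiency,Efficiency,1,1,1
Efficiency,Equity and Access,0.38,0.449,0.551
Efficiency,Effectiveness,0.302,0.35,0.405
Equity and Access,Efficiency,1.815,2.228,2.634
Equity and Access,Equity and Access,1,1,1
Equity and Access,Effectiveness,1.063,1.197,1.351
Effectiveness,Efficiency,2.472,2.853,3.315
Effectiveness,Equity and Access,0.74,0.835,0.941
Effectiveness,Effectiveness,1,1,1
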