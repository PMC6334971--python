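((Hsa,Sce),(Ddi,((Ath,(Tps,Ehu)),((Tva,Gin),Cme),((Tbr,(Ngr,Egr)),Sin))));
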