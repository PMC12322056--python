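condition,cd40_nM,bcr_nM,time_h,readout,fold
high_cd40,30,0,7,RelA,10
low_cd40,6,0,7,RelA,5
high_cd40,30,0,7,cRel,13
low_cd40,6,0,7,cRel,4
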