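module,index,reaction,rate,units,source,category
BCR receptor,1,"ANTIGEN ->",0.05,h-1,Fitted (antibody),degradation
BCR receptor,2,"-> BCR",4.93,nM h-1,Fitted,synthesis
BCR receptor,3,"BCR ->",1.43,h-1,Fitted,degradation
BCR receptor,4,"ANTIGEN + BCR -> ABCR",66,nM-1 h-1,Fitted,association
BCR receptor,5,"ABCR -> ANTIGEN + BCR",1.26,h-1,Fitted,dissociation
BCR receptor,6,"ABCR ->",0.35,h-1,Coulter et al,degradation
BCR receptor,7,"CBM + ABCR -> ACBM + ABCR",6.6,nM-1 h-1,Inoue et al,catalysis
BCR receptor,8,"ACBM -> CBM",0.126,h-1,Inoue et al,conversion
BCR receptor,9,"ACBM + IKK -> ICBM + IKK",0.181,nM-1 h-1,Inoue et al,catalysis
BCR receptor,10,"ICBM -> CBM",0.068,h-1,Inoue et al,conversion
CD40 receptor,11,"CD40L ->",0.05,h-1,Fitted (antibody),degradation
CD40 receptor,12,"-> CD40R",7.672,nM h-1,Fitted,synthesis
CD40 receptor,13,"CD40R ->",0.05,h-1,Tucker and Schwiebert,degradation
CD40 receptor,14,"CD40L + CD40R -> CD40LR",0.04,nM-1 h-1,Ceglia et al,association
CD40 receptor,15,"CD40LR -> CD40L + CD40R",11.3,h-1,Ceglia et al,dissociation
CD40 receptor,16,"CD40LR ->",0.17,h-1,Tucker and Schwiebert,degradation
CD40 receptor,17,"CD40LR + TRAF6_off -> CD40LR + TRAF6",0.1,nM-1 h-1,Cheng et al,catalysis
CD40 receptor,18,"TRAF6 -> TRAF6_off",7.5,h-1,Cheng et al,conversion
CD40 receptor,19,"-> TRAF3",10,nM h-1,Fitted,synthesis
CD40 receptor,20,"TRAF3 ->",0.5,h-1,Zhao et al,degradation
CD40 receptor,21,"CD40LR + TRAF3 -> CD40LR",10,nM-1 h-1,Fitted,catalysis
TAK1 dynamics,22,"ACBM + TAK1 -> ACBM + ATAK1",1050,nM-1 h-1,Shinohara et al,catalysis
TAK1 dynamics,23,"TRAF6 + TAK1 -> TRAF6 + ATAK1",60,nM-1 h-1,Cheng et al,catalysis
TAK1 dynamics,24,"IKK2 + TAK1 -> IKK2 + ATAK1",401.14,nM-1 h-1,Shinohara et al,catalysis
TAK1 dynamics,25,"IKK3 + TAK1 -> IKK3 + ATAK1",1182.86,nM-1 h-1,Shinohara et al,catalysis
TAK1 dynamics,26,"TAK1 -> ATAK1",249,h-1,Shinohara et al,conversion
TAK1 dynamics,27,"ATAK1 -> TAK1",258600,h-1,Shinohara et al,conversion
IKK dynamics,28,"ATAK1 + IKK_off -> ATAK1 + IKK2",80.72,h-1,Shinohara et al,catalysis
IKK dynamics,29,"IKK2 -> IKK_off",2175.6,h-1,Shinohara et al,conversion
IKK dynamics,30,"IKK2 -> IKK3",0.009,h-1,Shinohara et al,conversion
IKK dynamics,31,"IKK3 + IKK2 -> IKK3 + IKK3",2094,h-1,Shinohara et al,catalysis
IKK dynamics,32,"IKK3 -> IKK2",53844,h-1,Shinohara et al,conversion
IKK dynamics,33,"IKK3 -> IIKK",2528.4,h-1,Shinohara et al,conversion
IKK dynamics,34,"IIKK -> IKK_off",957.6,h-1,Shinohara et al,conversion
NIK dynamics,35,"-> NIK",12,nM h-1,Mitchell et al,synthesis
NIK dynamics,36,"NIK ->",0.231,h-1,Mitchell et al,degradation
NIK dynamics,37,"TRAF3 + NIK -> TRAF3",2,nM-1 h-1,Qing et al,catalysis
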