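study_id,modality,SP6,SP8,SP10,CV3,CV4,CV6,CV12,GV3,GV4,GV20,GV24,ST25,ST29,ST36,KI3,KI7,KI12,LR3,GB1,GB34,BL17,BL20,BL23,BL32,BL33,EX-B8,EX-CA1
Zhou2016,acupuncture,1,0,0,0,1,1,0,0,1,0,0,0,0,1,1,1,0,1,0,1,1,0,1,0,0,1,1
Xu2016,acupuncture,1,0,1,0,1,0,0,0,0,1,0,0,0,1,1,0,0,1,0,0,0,1,0,0,0,0,0
Fernando2016,acupuncture,0,0,1,0,1,0,1,0,0,1,1,1,0,1,1,0,1,1,1,0,0,0,1,1,0,1,0
Yan2015,acupuncture,0,1,1,0,1,0,0,0,0,0,0,0,1,1,1,0,0,0,0,0,0,0,1,0,0,0,1
Lian2015,electro-acupuncture,1,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
Wang2016,electro-acupuncture,0,0,0,0,1,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,1,0,1
Zhou2013,electro-acupuncture,0,0,0,0,1,0,0,0,0,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,1,0,0
Chen2009,electro-acupuncture,1,0,0,0,1,0,0,0,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0
Liu2008,electro-acupuncture,1,0,0,1,1,0,0,0,0,0,0,0,0,0,1,0,0,1,0,0,0,0,0,0,0,0,1
Zheng2015,TEAS,1,0,0,1,1,0,0,0,1,1,0,1,0,0,0,0,0,0,0,0,0,0,1,0,0,0,1
Lian2014,TEAS,1,0,0,1,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
Chen2011,TEAS,1,0,0,1,1,0,0,1,1,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
Zhu2012,TEAS,1,0,0,1,1,0,0,1,1,0,0,1,0,0,0,0,0,0,0,0,0,0,1,0,0,0,1
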