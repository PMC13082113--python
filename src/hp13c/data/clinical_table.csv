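patient_id,age,sex,diagnosis,treatment,pfs6_flag,os_years,baseline_acquired,followup_months
P1,29,F,rAS4,"Bevacizumab + [RT, TMZ]",1,0.7,No,"2m, 3m, 5m"
P2,39,M,rAS4,Bevacizumab,0,5.0,No,1m
P3,55,M,rGBM,"Bevacizumab + [CCNU, Afatinib, Abemaciclib]",1,0.8,Yes,4m
P4,63,M,rGBM,Bevacizumab + CCNU,0,0.9,Yes,"1m, 3m"
P5,56,F,rGBM,"Bevacizumab + [Carboplatin, Trametinib]",1,0.3,Yes,1m
P6,55,M,rGBM,"Everolimus + [CCNU, Trametinib, Abeciclib]",1,0.7,Yes,4m
P7,62,M,rGBM,"Everolimus + [TMZ, Olaparib]",1,0.8,No,2m
P8,45,M,rGBM,"Everolimus + [TMZ, Afatinib]",1,0.9,Yes,2m
P9,68,M,rGBM,"Everolimus + [CCNU, Dasatinib]",1,0.6,No,"2m, 4m"
P10,33,M,rAS4,"TMZ + [Olaparib, Abemaciclib]",0,1.4,No,"2m, 3m"
P11,69,F,rGBM,"CCNU + [Afatinib, Abemaciclib]",0,1.1,Yes,"2m, 4m, 5m"
P12,57,M,rGBM,"TMZ + [Afatinib, Olaparib]",0,3.7,No,"2m, 4m"
P13,58,F,rGBM,"CCNU + [Afatanib, Abecliclab]",0,0.4,Yes,2m
P14,40,F,rGBM,"TMZ + [Olaparib, Abemaciclib]",0,3.0,No,2m
P15,57,M,rGBM,"TMZ + [Propranolol, Trametinib, Abemaciclib]",1,1.1,Yes,4m
P16,55,M,rGBM,CCNU + Afatinib,1,0.6,Yes,2m
P17,55,F,rGBM,"TMZ + [Afatinib, Olaparib]",0,1.6,Yes,4m
P18,40,M,rGBM,"CCNU + [Afatinib, Abemaciclib]",1,2.0,No,2m
P19,59,F,rGBM,TMZ,0,1.1,Yes,"1m, 3m"
P20,50,M,rGBM,CCNU,1,0.3,Yes,1m
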