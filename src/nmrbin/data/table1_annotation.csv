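bin_label,metabolite,origin,tentative,shared
7.93,Xanthine,diet,False,False
1.52,Butyrate,microbiome,False,False
0.88,Butyrate,microbiome,False,False
2.18,Butyrate,microbiome,False,True
2.18,Propionate,microbiome,False,True
1.06,Propionate,microbiome,False,False
5.64,UDP-glucose,microbiome,False,False
5.63,UDP-glucose,microbiome,False,False
5.62,UDP-glucose,microbiome,False,False
0.84,Valerate,microbiome,True,False
5.94,Uridine derivates,microbiome,False,False
6.13,Uridine derivates,microbiome,False,False
6.12,Uridine derivates,microbiome,False,False
6.11,Uridine derivates,microbiome,False,False
7.89,Uridine derivates,microbiome,False,False
7.86,Uridine derivates,microbiome,False,False
0.77,Bile acids,endogenous,True,False
0.76,Bile acids,endogenous,True,False
0.75,Bile acids,endogenous,True,False
0.74,Bile acids,endogenous,True,False
0.73,Bile acids,endogenous,True,False
6.65,Kynurenic acid,endogenous,False,False
7.82,Kynurenic acid,endogenous,False,False
7.68,Kynurenic acid,endogenous,False,False
7.49,Kynurenic acid,endogenous,False,False
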