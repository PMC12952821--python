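compound,odor_description,rt_min,ri,odor_threshold_ug_L,relative_content_pct,concentration_ug_L,oav,vip,origin
"Formic acid, butyl ester","Fruity, wine-like, sweet, with a slight waxy note",13.546,724,0.37,0.093,,3.113,0.121,Esterification
"Butanoic acid, 2-methyl-","Fruity, wine-like, sweet, with a slight waxy note",68.061,861,0.02,0.025,,15.229,0.25,Esterification
"1,2-Ethanediol, diacetate","Fruity, wine-like, sweet, with a slight waxy note",55.047,994,1.8,0.914,,6.285,1.316,Esterification
"Pyrazine, methyl-","Nutty, caramel-like",41.69,831,1.9,0.158,,1.028,0.188,Maillard reaction
"Pyrazine, 2,6-dimethyl-","Nutty, caramel-like",45.829,917,ND,0.143,,0,2.397,Maillard reaction
"2-Propanone, 1-hydroxy-","Nutty, caramel-like",46.263,917,1.72,0.119,,1.031,0.141,Maillard reaction
"Pyrazine, 2-ethyl-5-methyl-","Nutty, caramel-like",50.715,1005,0.036,0.022,,7.513,0.182,Maillard reaction
Phenylethyl alcohol,"Fruity, green/grassy, woody",81.603,1116,0.012,0.086,,88.38,0.16,Chlorophyll degradation
Neophytadiene,"Fruity, green/grassy, woody",81.878,1837,ND,1.246,,0,2.015,Chlorophyll degradation
Acetic acid,"Amine odor, sour odor, unpleasant odor",54.38,610,0.013,1.005,,957.47,2.082,Short-chain fatty acids
"Butanoic acid, 3-methyl-","Amine odor, sour odor, unpleasant odor",68.061,863,0.0018,0.047,,323.69,0.132,Short-chain fatty acids
"Retinol, acetate","Amine odor, sour odor, unpleasant odor",100.593,2555,ND,2.613,,0,1.893,Carotenoid degradation
Hydroxylamine,Smoky/Unknown flavor,16.152,,ND,1.629,,0,2.35,Tobacco alkaloids and their metabolites
Glycidol,Smoky/Unknown flavor,55.235,755,ND,0.649,,0,1.757,Epoxide hydrolysis
Propylene glycol,Smoky/Unknown flavor,64.604,740,16,5.963,,4.614,4.639,
"Pyridine, 3-(1-methyl-2-pyrrolidinyl)-, (S)-",Smoky/Unknown flavor,79.68,1361,16,1.42,,0,0.214,Diol oxidation
Phenol,Smoky/Unknown flavor,86.074,980,0.00017,44.72,,1.178,3.086,Amide bond hydrolysis
Triacetin,Smoky/Unknown flavor,89.373,1344,ND,25.42,,0,4.765,Tobacco alkaloids and their metabolites
"Pyridine, 3-(3,4-dihydro-2h-pyrrol-5-yl)-",Smoky/Unknown flavor,96.156,1427,ND,2.005,,0,1.510,Esterification
"1,2,3-Propanetriol, 1-acetate",Smoky/Unknown flavor,96.725,1093,ND,0.183,,13336.36,0.255,Esterification
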