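compound,odor_description,rt_min,ri,odor_threshold_ug_L,relative_content_pct,concentration_ug_L,oav,vip,origin
"2-Propanone, 1-hydroxy-","Sweet, caramel, buttery, toasted/Nutty (almond-like), and toasty/Bready, with a slight sourness/Tang",4.492,665,ND,3.499,,0,1.185,Maillard reaction
"2-Propanone, 1-(acetyloxy)-","Sweet, caramel, buttery, toasted/Nutty (almond-like), and toasty/Bready, with a slight sourness/Tang",8.658,870,ND,0.989,,0,1.332,Maillard reaction
"1,2-Cyclopentanedione, 3-methyl-","Sweet, caramel, buttery, toasted/Nutty (almond-like), and toasty/Bready, with a slight sourness/Tang",13.683,1043,0.026,0.502,,10.318,0.523,Maillard reaction
Furaneol,"Sweet, caramel, buttery, toasted/Nutty (almond-like), and toasty/Bready, with a slight sourness/Tang",15.074,1070,0.0015,0.128,,41.517,0.373,Maillard reaction
Indole,"Floral, black tea, herbal, fruity",21.239,1295,0.04,0.685,,9.566,0.744,Shikimate pathway
"7-Oxabicyclo [4.1.0]heptan-3-ol, 6-(3-hydroxy-1-butenyl)-1,5,5-trimethyl-","Floral, black tea, herbal, fruity",29.854,1674,ND,1.902,,0,1.003,Chlorophyll degradation
Neophytadiene,"Floral, black tea, herbal, fruity",33.243,1837,ND,1.80,,0,0.797,Chlorophyll degradation
Phytol,"Floral, black tea, herbal, fruity",38.377,2114,0.64,0.823,,0.705,1.228,Chlorophyll degradation
Acetic acid,"Sour, medicinal, amine-like odor",4.032,610,0.013,2.653,,114.36,0.62,Maillard reaction
Phenol,"Sour, medicinal, amine-like odor",12.707,980,0.021,2.113,,54.987,0.923,Lignin degradation
"Phenol, 2-methoxy-","Sour, medicinal, amine-like odor",15.183,1090,0.0015,0.174,,61.97,0.555,Lignin degradation
"Pyrrolidine, 1-(1-pentenyl)-","Sour, medicinal, amine-like odor",19.423,,ND,0.530,,0,1.072,Maillard reaction
"2-Nonen-1-ol, (E)-","Typical fatty, cucumber peel, and waxy notes",15.551,1176,0.209,1.120,,2.985,1.123,Lipoxygenase pathway
4-Pyridinol,Smoky/Unknown flavor,17.272,1154,ND,2.448,,0,1.417,Hydroxylated pyridine derivatives
3-Pyridinol,Smoky/Unknown flavor,17.433,,ND,1.937,,0,1.358,Hydroxylated pyridine derivatives
Catechol,Smoky/Unknown flavor,19.176,1205,8,1.217,,0.076,1.853,Pyrolysis products of lignin
"Pyridine, 2-(1-methyl-2-pyrrolidinyl)-",Smoky/Unknown flavor,21.92,1354,ND,22.07,,0,3.091,Tobacco alkaloids and their metabolites
"Pyridine, 3-(1-methyl-2-pyrrolidinyl)-, (S)-",Smoky/Unknown flavor,22.523,1361,470,30.659,,0.035,3.257,Tobacco alkaloids and their metabolites
"Pyridine, 3-(3,4-dihydro-2h-pyrrol-5-yl)-",Smoky/Unknown flavor,24.309,1427,ND,3.274,,0,2.128,Tobacco alkaloids and their metabolites
"2H-1,2-oxazine, tetrahydro-2-methyl-6-(3-pyridinyl)-, (−)-",Smoky/Unknown flavor,25.523,,ND,0.344,,0,1.007,Tobacco alkaloids and their metabolites
"1,2,3,6-Tetrahydro-2,3′-bipyridine",Smoky/Unknown flavor,26.52,,ND,0.275,,0,1.120,Tobacco alkaloids and their metabolites
"2,3′-dipyridyl",Smoky/Unknown flavor,26.858,1556,ND,2.133,,0,1.129,Tobacco alkaloids and their metabolites
Cotinine,Smoky/Unknown flavor,30.824,1721,ND,1.211,,0,1.284,Tobacco alkaloids and their metabolites
n-Hexadecanoic acid,Smoky/Unknown flavor,35.624,1968,ND,1.078,,0,1.18,Fatty acids
Thunbergol,Smoky/Unknown flavor,37.852,2073,ND,0.386,,0,1.002,Fatty acids
"4,8,13-Cyclotetradecatriene-1,3-diol, 1,5,9-trimethyl-12-(1-methylethyl)-",Smoky/Unknown flavor,37.878,,ND,0.447,,0,1.009,Degradation products of cembranoids
Octadecanoic acid,Smoky/Unknown flavor,39.261,2172,ND,0.291,,0,0.694,Degradation products of cembranoids
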