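compound,odor_description,rt_min,ri,odor_threshold_ug_L,relative_content_pct,concentration_ug_L,oav,vip,origin
"Cyclohexene, 1-methyl-4-(1-methylethenyl)-, (S)-","Woody, citrus (lemon, citrus), fresh pine, floral (rose, saffron, violet), grassy, spicy, herbal/Medicinal, sweet, creamy/Fatty",10.268,1031,0.034,0.075,,0.899,0.578,Terpenoid biosynthesis
"Bicyclo [3.1.1]heptane, 6,6-dimethyl-2-methylene-, (1S)-","Woody, citrus (lemon, citrus), fresh pine, floral (rose, saffron, violet), grassy, spicy, herbal/Medicinal, sweet, creamy/Fatty",11.996,,4.16,3.435,,0.068,1.025,Terpenoid biosynthesis
D-limonene,"Woody, citrus (lemon, citrus), fresh pine, floral (rose, saffron, violet), grassy, spicy, herbal/Medicinal, sweet, creamy/Fatty",12.905,,0.034,4.396,,0.899,1.182,Terpenoid biosynthesis
"Cyclohexanol, 1-methyl-4-(1-methylethenyl)-, acetate","Woody, citrus (lemon, citrus), fresh pine, floral (rose, saffron, violet), grassy, spicy, herbal/Medicinal, sweet, creamy/Fatty",13.077,1317,ND,3.356,,0,1.117,Terpenoid biosynthesis
Nonanal,"Woody, citrus (lemon, citrus), fresh pine, floral (rose, saffron, violet), grassy, spicy, herbal/Medicinal, sweet, creamy/Fatty",15.44,1104,0.001,0.057,,604.732,0.143,Fatty acid oxidation
Megastigmatrienone,"Woody, citrus (lemon, citrus), fresh pine, floral (rose, saffron, violet), grassy, spicy, herbal/Medicinal, sweet, creamy/Fatty",31.508,1473,ND,1.306,,0,0.759,Carotenoid degradation
"3,7,11,15-Tetramethyl-2-hexadecen-1-ol","Woody, citrus (lemon, citrus), fresh pine, floral (rose, saffron, violet), grassy, spicy, herbal/Medicinal, sweet, creamy/Fatty",39.35,2116,ND,8.022,,0,3.152,Chlorophyll/Phytol degradation
Neophytadiene,"Woody, citrus (lemon, citrus), fresh pine, floral (rose, saffron, violet), grassy, spicy, herbal/Medicinal, sweet, creamy/Fatty",38.237,1837,ND,16.910,,0,3.799,Chlorophyll/Phytol degradation
"6-Quinolinamine, 2-methyl-",Amine-like/Aminic,28.349,,ND,1.682,,0,1.512,Maillard reaction
"Pyridine, 3-(1-methyl-2-pyrrolidinyl)-, (S)-",Smoky,24.39,1361,470,42.828,,1.086,7.684,Pyrolysis products of alkaloids
"1,5,9,11-Tridecatetraene, 12-methyl-, (E, E)-",Odorless/No distinct odor,13.781,,ND,1.247,,0,1.176,Carotenoid degradation
"Pyridine, 3-(3,4-dihydro-2h-pyrrol-5-yl)-",Odorless/No distinct odor,26.747,1427,ND,1.382,,0,0.620,Pyrolysis products of alkaloids
"2,3′-dipyridyl",Odorless/No distinct odor,30.009,1556,ND,6.058,,0,1.948,Pyrolysis products of alkaloids
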