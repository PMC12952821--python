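compound,avg_sbse,avg_py,avg_smokiness,dte,rir_smk_sbse,rir_smk_py,pci,notes
"1,2,3-Propanetriol, 1-acetate",0.0709,0,26.54,374.3,374.3,—,0,"High-efficiency release, no thermogenesis"
"2-Propanone, 1-hydroxy-",0,2.36,14.32,—,—,6.07,0.165,"Complete thermogenesis, partial entry into flue gas"
"3,7,11,15-Tetramethyl-2-hexadecen-1-ol",0.071,0,0.0438,0.617,0.617,—,0,Present in leaves but limited release
Acetic acid,0.0033,1.22,12.86,3897,3897,10.54,0.095,"Extremely enriched in flue gas, primarily thermogenic"
"Butanoic acid, 2-methyl-",0.014,0,0.2209,15.78,15.78,—,0,Primordial release type
"Butanoic acid, 3-methyl-",0.0319,0,0.5362,16.8,16.8,—,0,Primordial release type
Glycidol,0.0466,0,13.17,282.6,282.6,—,0,"High-efficiency release, non-thermogenic"
Hydroxylamine,0.0493,0,16.93,343.4,343.4,—,0,"High-efficiency release, non-thermogenic"
Neophytadiene,35.12,1.26,15.44,0.439,0.439,12.25,0.0816,"High in-situ, low transfer, weak thermogenesis"
Phenol,0.1435,1.1812,2.221,15.48,15.48,1.88,0.532,Significant thermogenesis + high-efficiency release
"Pyrazine, methyl-",0.0481,0,1.939,40.31,40.31,—,0,"High release efficiency, thermal generation"
"Pyrazine, 2,6-dimethyl-",0.0466,0,2.463,52.85,52.85,—,0,"High release efficiency, thermal generation"
"Pyrazine, 2-ethyl-5-methyl-",0.0305,0,0.2839,9.31,9.31,—,0,"High release efficiency, thermal generation"
"Pyridine, 3-(1-methyl-2-pyrrolidinyl)-, (S)-",355.15,20.87,653.89,1.84,1.84,31.33,0.0319,"Primarily from primary release, minor thermal generation"
"Pyridine, 3-(3,4-dihydro-2h-pyrrol-5-yl)-",3.032,1.7698,42.97,14.17,14.17,24.28,0.0412,High release efficiency + moderate thermal generation
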