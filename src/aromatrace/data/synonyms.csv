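raw_name,canonical_name
Phytol,"3,7,11,15-Tetramethyl-2-hexadecen-1-ol"
Nicotine,"Pyridine, 3-(1-methyl-2-pyrrolidinyl)-, (S)-"
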