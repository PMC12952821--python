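notes,fate_label
"High-efficiency release, no thermogenesis",EFFICIENT_RELEASE
"Complete thermogenesis, partial entry into flue gas",THERMALLY_GENERATED_PARTIAL_TRANSFER
Present in leaves but limited release,EQUAL_TRANSFER
"Extremely enriched in flue gas, primarily thermogenic",THERMOGENESIS_PLUS_RELEASE
Primordial release type,EFFICIENT_RELEASE
"High-efficiency release, non-thermogenic",EFFICIENT_RELEASE
"High in-situ, low transfer, weak thermogenesis",PARTIAL_LOSS
Significant thermogenesis + high-efficiency release,THERMOGENESIS_PLUS_RELEASE
"High release efficiency, thermal generation",EFFICIENT_RELEASE
"Primarily from primary release, minor thermal generation",EQUAL_TRANSFER
High release efficiency + moderate thermal generation,EFFICIENT_RELEASE
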