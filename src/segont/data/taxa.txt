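# Synthetic offline taxon name list for the segont package.
# One record per line: scientific name <TAB> local identifier.
# Identifiers are fixture-local, not real namebank ids.
Galanthus elwesii	tx:0001
Galanthus nivalis	tx:0002
Chamerion angustifolium	tx:0003
Arabidopsis thaliana	tx:0004
Zea mays	tx:0005
Oryza sativa	tx:0006
Solanum lycopersicum	tx:0007
Persea americana	tx:0008
Laurus nobilis	tx:0009
Cinnamomum verum	tx:0010
Quercus robur	tx:0011
Pinus taeda	tx:0012
Helianthus annuus	tx:0013
Vitis vinifera	tx:0014
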