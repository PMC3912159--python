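# Per-species MXE cluster inventory of the metazoan muscle myosin
# heavy chain survey (states: P present, A absent, U unknown).
species	cluster-0	cluster-1	cluster-2	cluster-3	cluster-4	cluster-5	cluster-6	cluster-7	cluster-8	cluster-9	cluster-10	cluster-11
Mnemiopsis_leidyi	P	A	A	A	A	A	A	A	A	A	A	A
Schistosoma_mansoni	A	A	A	A	A	A	A	A	P	A	A	A
Schmidtea_mediterranea	A	A	A	A	A	A	A	A	P	A	A	A
Helobdella_robusta	A	A	A	A	A	A	A	A	A	A	A	A
Capitella_teleta	A	A	A	P	P	P	P	A	P	P	A	P
Crassostrea_gigas	A	A	P	P	A	P	A	A	A	A	A	P
Aplysia_californica	A	A	P	P	A	A	A	A	P	A	A	P
Biomphalaria_glabrata	A	A	P	P	A	A	A	A	P	A	A	A
Lottia_gigantea	A	A	P	P	A	P	A	A	P	A	A	A
Caenorhabditis_elegans	A	A	A	A	A	A	A	A	A	A	A	A
Parasteatoda_tepidariorum	A	A	A	A	A	P	A	P	A	P	A	P
Centruroides_sculpturatus	A	A	A	A	A	P	A	P	A	P	P	A
Ixodes_scapularis	A	P	P	A	A	P	A	P	A	P	P	P
Metaseiulus_occidentalis	A	A	A	A	A	A	A	A	A	A	P	P
Tetranychus_urticae	A	A	A	A	A	P	A	P	A	P	P	P
Strigamia_maritima	A	P	A	A	A	P	A	P	P	P	P	A
Daphnia_pulex	A	P	P	A	A	P	P	P	P	P	P	P
Lepeophtheirus_salmonis	A	A	A	A	A	A	A	A	A	A	A	A
Pediculus_humanus	A	P	A	A	A	P	A	P	P	A	A	P
Tribolium_castaneum	A	P	A	A	A	P	A	P	P	A	P	P
Drosophila_melanogaster	A	P	A	A	A	P	A	P	A	A	P	P
Strongylocentrotus_purpuratus	A	A	A	A	A	A	A	A	P	A	A	A
Saccoglossus_kowalevskii	A	A	A	A	A	A	A	A	P	A	A	A
Ciona_intestinalis	A	A	A	A	A	A	A	A	A	A	A	A
Homo_sapiens	A	A	A	A	A	A	A	A	A	A	A	A
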