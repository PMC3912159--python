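(Mnemiopsis_leidyi,((((Schistosoma_mansoni,Schmidtea_mediterranea)Platyhelminthes,((Helobdella_robusta,Capitella_teleta)Annelida,(Crassostrea_gigas,(Aplysia_californica,(Biomphalaria_glabrata,Lottia_gigantea)Panpulmonata)Gastropoda)Mollusca)AnnelidaMollusca)Lophotrochozoa,(Caenorhabditis_elegans,(((Parasteatoda_tepidariorum,Centruroides_sculpturatus)Arachnopulmonata,((Ixodes_scapularis,Metaseiulus_occidentalis)Parasitiformes,Tetranychus_urticae)Acari)Chelicerata,(Strigamia_maritima,((Daphnia_pulex,Lepeophtheirus_salmonis)Crustacea,(Pediculus_humanus,(Tribolium_castaneum,Drosophila_melanogaster)Holometabola)Insecta)Pancrustacea)Mandibulata)Arthropoda)Ecdysozoa)Protostomia,((Strongylocentrotus_purpuratus,Saccoglossus_kowalevskii)Ambulacraria,(Ciona_intestinalis,Homo_sapiens)Chordata)Deuterostomia)Bilateria)Eumetazoa;
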