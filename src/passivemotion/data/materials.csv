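material,density_kg_m3,delta_rho_kg_m3,kind
Water,998,0,fluid
Bacterial Cell,1100,102,biological
Diatom Cell,1150,152,biological
Carnalite,1570,572,mineral
Suspended Ocean Minerals,1600,602,mineral
Borax (Decahydrate),1700,702,mineral
Silica,2080,1082,mineral
Calcium Carbonate,2710,1712,mineral
Alumina,2930,1932,mineral
Polystyrene,1050,52,polymer
Anabaena Gas Vesicles,119,-879,biological
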