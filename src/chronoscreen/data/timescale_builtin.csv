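# Built-in chronostratigraphic lookup table: unit name -> age interval (MYA).
# Values follow the standard international chart (stage boundaries rounded to
# the published decimal precision). Replaceable via GeoTimeScale.from_csv().
# version: chronoscreen-builtin-1
unit,rank,min_mya,max_mya
Holocene,epoch,0.0,0.0117
Pleistocene,epoch,0.0117,2.58
Calabrian,stage,0.774,1.8
Gelasian,stage,1.8,2.58
Pliocene,epoch,2.58,5.333
Piacenzian,stage,2.58,3.6
Zanclean,stage,3.6,5.333
Miocene,epoch,5.333,23.03
Messinian,stage,5.333,7.246
Tortonian,stage,7.246,11.63
Serravallian,stage,11.63,13.82
Langhian,stage,13.82,15.97
Burdigalian,stage,15.97,20.44
Aquitanian,stage,20.44,23.03
Oligocene,epoch,23.03,33.9
Chattian,stage,23.03,27.82
Rupelian,stage,27.82,33.9
Eocene,epoch,33.9,56.0
Priabonian,stage,33.9,37.71
Bartonian,stage,37.71,41.2
Lutetian,stage,41.2,47.8
Ypresian,stage,47.8,56.0
Paleocene,epoch,56.0,66.0
Thanetian,stage,56.0,59.2
Selandian,stage,59.2,61.6
Danian,stage,61.6,66.0
Late Cretaceous,epoch,66.0,100.5
Maastrichtian,stage,66.0,72.1
Campanian,stage,72.1,83.6
Santonian,stage,83.6,86.3
Coniacian,stage,86.3,89.8
Turonian,stage,89.8,93.9
Cenomanian,stage,93.9,100.5
Early Cretaceous,epoch,100.5,145.0
Albian,stage,100.5,113.0
Aptian,stage,113.0,125.0
Barremian,stage,125.0,129.4
Hauterivian,stage,129.4,132.9
Valanginian,stage,132.9,139.8
Berriasian,stage,139.8,145.0
Late Jurassic,epoch,145.0,163.5
Tithonian,stage,145.0,152.1
Kimmeridgian,stage,152.1,157.3
Oxfordian,stage,157.3,163.5
Middle Jurassic,epoch,163.5,174.1
Callovian,stage,163.5,166.1
Bathonian,stage,166.1,168.3
Bajocian,stage,168.3,170.3
Aalenian,stage,170.3,174.1
Early Jurassic,epoch,174.1,201.3
Toarcian,stage,174.1,182.7
Pliensbachian,stage,182.7,190.8
Sinemurian,stage,190.8,199.3
Hettangian,stage,199.3,201.3
Late Triassic,epoch,201.3,237.0
Rhaetian,stage,201.3,208.5
Norian,stage,208.5,227.0
Carnian,stage,227.0,237.0
Middle Triassic,epoch,237.0,247.2
Ladinian,stage,237.0,242.0
Anisian,stage,242.0,247.2
Early Triassic,epoch,247.2,251.902
Olenekian,stage,247.2,251.2
Induan,stage,251.2,251.902
Quaternary,period,0.0,2.58
Neogene,period,2.58,23.03
Paleogene,period,23.03,66.0
Cretaceous,period,66.0,145.0
Jurassic,period,145.0,201.3
Triassic,period,201.3,251.902
Permian,period,251.902,298.9
Carboniferous,period,298.9,358.9
Devonian,period,358.9,419.2
Silurian,period,419.2,443.8
Ordovician,period,443.8,485.4
Cambrian,period,485.4,538.8
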