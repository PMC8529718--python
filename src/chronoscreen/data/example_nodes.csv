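node_label,taxonA,taxonB
node2,Orectolobus ornatus,Brachaelurus waddi
node3,Ginglymostoma cirratum,Nebrius ferrugineus
node4,Ginglymostoma cirratum,Rhincodon typus
node5,Stegostoma tigrinum,Rhincodon typus
node6,Ginglymostoma cirratum,Hemiscyllium ocellatum
node7,Chiloscyllium griseum,Hemiscyllium ocellatum
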