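# Example taxonomy -> node assignment rules for the carpet shark
# (Orectolobiformes) reference configuration. The family -> node map is a
# proposal: node definitions pin down which divergence each label means
# (see example_nodes.csv), but stem-vs-crown placement per family is a
# judgement call the user must confirm against their own tree.
family_to_node:
  Orectolobidae: node2
  Brachaeluridae: node2
  Parascylliidae: node2
  Ginglymostomatidae: node3
  Rhincodontidae: node4
  Stegostomatidae: node5
  Hemiscylliidae: node7
genus_overrides:
  # placed with the zebra sharks (node5): phylogenetic placement of this
  # genus contradicts its described family
  Pseudoginglymostoma: node5
exclude:
  # extinct side lineage; not assignable to a divergence among extant taxa
  - Pararhincodon
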