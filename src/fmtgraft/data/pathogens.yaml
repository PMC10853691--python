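# Default donor-screening list: known or suspected bacterial pathogens of
# bottlenose dolphins. Species entries match exact binomials; genus entries
# match every species of the genus (E. coli and Clostridium are screened at
# genus level; toxin assays are out of scope for sequence-based screening).
# "Erysipelothrix rhusopathiae" is also commonly spelled "rhusiopathiae".
pathogens:
  - {name: Erysipelothrix rhusopathiae, match_level: species}
  - {name: Brucella ceti, match_level: species}
  - {name: Mycobacterium marinum, match_level: species}
  - {name: Mycobacterium chelonae, match_level: species}
  - {name: Mycobacterium abscessus, match_level: species}
  - {name: Nocardia asteroides, match_level: species}
  - {name: Nocardia farcinica, match_level: species}
  - {name: Nocardia brasiliensis, match_level: species}
  - {name: Nocardia cyriacigeorgica, match_level: species}
  - {name: Nocardia levis, match_level: species}
  - {name: Staphylococcus aureus, match_level: species}
  - {name: Streptococcus phocae, match_level: species}
  - {name: Streptococcus zooepidemicus, match_level: species}
  - {name: Streptococcus iniae, match_level: species}
  - {name: Salmonella, match_level: genus}
  - {name: Mycoplasma, match_level: genus}
  - {name: Bartonella, match_level: genus}
  - {name: Clostridium, match_level: genus}
  - {name: Escherichia, match_level: genus}
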