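# Species vocabulary for urban bat acoustic surveys: 11 species plus 3
# acoustic groups whose members cannot be separated reliably by call
# structure.  Functional guilds follow standard foraging-niche
# classifications (edge-space vs open-space foragers); taxa in neither
# guild are still counted in total activity and richness.
species:
  - "P. pipistrellus"
  - "P. pygmaeus"
  - "P. kuhlii/P. nathusii"
  - "B. barbastellus"
  - "M. alcathoe"
  - "M. brandtii/M. mystacinus"
  - "N. noctula"
  - "E. nilssonii"
  - "H. savii"
  - "N. leisleri"
  - "M. daubentonii"
  - "M. nattereri"
  - "V. murinus"
  - "Plecotus auritus/P. austriacus"

# Raw labels folded into acoustic groups before any richness counting.
acoustic_group_merges:
  "P. kuhlii": "P. kuhlii/P. nathusii"
  "P. nathusii": "P. kuhlii/P. nathusii"
  "M. brandtii": "M. brandtii/M. mystacinus"
  "M. mystacinus": "M. brandtii/M. mystacinus"
  "Plecotus auritus": "Plecotus auritus/P. austriacus"
  "Plecotus austriacus": "Plecotus auritus/P. austriacus"

functional_groups:
  edge_space:
    - "P. pipistrellus"
    - "P. pygmaeus"
    - "P. kuhlii/P. nathusii"
    - "B. barbastellus"
    - "M. alcathoe"
    - "M. brandtii/M. mystacinus"
  open_space:
    - "N. noctula"
    - "E. nilssonii"
    - "H. savii"

representative_species:
  open_space: "N. noctula"
  edge_space: "P. pygmaeus"
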