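phylum	n_species_surveyed
Annelida	7
Arthropoda	30
Chordata	10
Echinodermata	6
Mollusca	10
Nematoda	10
Platyhelminthes	6
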