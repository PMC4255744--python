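# Example laboratory configuration.
#
# This is lab-local knowledge, not part of the action catalog: equipment,
# biochemical entities with external IDs, abbreviation conventions, and
# default settings for ambiguous tokens.  Entity IDs for well-known
# chemicals use NCBI PubChem compound IDs; working materials without a
# public accession use lab-internal IDs.
equipment:
- name: incubator
  aliases: [CO2 incubator]
- name: water bath
- name: orbital shaker
  aliases: [shaker platform]
- name: 10 ml glass pipette
- name: centrifuge tube
- name: ice bucket
- name: fume hood

entities:
- name: Trichloroacetic acid
  aliases: []
  id_source: NCBI Pubchem
  id_value: "6421"
- name: Dimethylsulfoxide
  aliases: []
  id_source: NCBI Pubchem
  id_value: "679"
- name: Bovine Serum Albumin
  aliases: [BSA solution]
  id_source: lab-internal
  id_value: "BSA-01"
- name: bFGF
  id_source: lab-internal
  id_value: "GF-bFGF"
- name: EGF
  id_source: lab-internal
  id_value: "GF-EGF"
- name: yeast growth culture
  id_source: lab-internal
  id_value: "CUL-Y1"
- name: phosphate-buffered saline
  aliases: []
  id_source: NCBI Pubchem
  id_value: "24978514"
- name: ethanol
  id_source: NCBI Pubchem
  id_value: "702"
- name: complete medium
  id_source: lab-internal
  id_value: "MED-C1"
- name: cell suspension
  id_source: lab-internal
  id_value: "CUL-S1"

abbreviations:
  TCA: Trichloroacetic acid
  DMSO: Dimethylsulfoxide
  BSA: Bovine Serum Albumin
  PBS: phosphate-buffered saline
  "ON": overnight  # quoted: bare ON is a YAML 1.1 boolean
  O/N: overnight
  RT: room temperature

defaults:
  overnight: {value: 16, unit: hour}
  room temperature: {value: 22, unit: "°C"}
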