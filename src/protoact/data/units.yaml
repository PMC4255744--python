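# Curated unit table: surface symbol, descriptor kind hinted when the unit
# appears with a number, Units Ontology accession (null where UO defines
# none), and accepted surface aliases.  Symbols are matched case-sensitively
# after text normalization (µ -> μ, "° C" -> "°C").
units:
- symbol: "°C"
  kind: temperature
  uo: UO:0000027
  aliases: ["℃", "degC"]
- symbol: "°F"
  kind: temperature
  uo: UO:0000195
- symbol: K
  kind: temperature
  uo: UO:0000012
- symbol: s
  kind: period
  uo: UO:0000010
  aliases: [sec, second, seconds]
- symbol: min
  kind: period
  uo: UO:0000031
  aliases: [minute, minutes]
- symbol: h
  kind: period
  uo: UO:0000032
  aliases: [hr, hrs, hour, hours]
- symbol: day
  kind: period
  uo: UO:0000033
  aliases: [days]
- symbol: "μL"
  kind: volume
  uo: UO:0000101
  aliases: [uL, ul]
- symbol: mL
  kind: volume
  uo: UO:0000098
  aliases: [ml]
- symbol: L
  kind: volume
  uo: UO:0000099
- symbol: rpm
  kind: speed
  uo: null
- symbol: "×g"
  kind: speed
  uo: null
  aliases: ["x g", xg]
- symbol: "%"
  kind: concentration
  uo: UO:0000187
- symbol: "μg/mL"
  kind: concentration
  uo: UO:0000274
  aliases: [ug/mL, ug/ml, "μg/ml"]
- symbol: mg/mL
  kind: concentration
  uo: UO:0000176
  aliases: [mg/ml]
- symbol: M
  kind: concentration
  uo: UO:0000062
- symbol: mM
  kind: concentration
  uo: UO:0000063
- symbol: "μM"
  kind: concentration
  uo: UO:0000064
  aliases: [uM]
- symbol: "μg"
  kind: null
  uo: UO:0000023
  aliases: [ug]
- symbol: mg
  kind: null
  uo: UO:0000022
- symbol: g
  kind: null
  uo: UO:0000021
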