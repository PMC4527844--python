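{
 "_note": "Physico-chemical residue classes used for consensus fallback symbols, following the Taylor-style sets used by the MView consensus engine. Classes are evaluated in the order listed (most specific first: ascending member count, ties broken by symbol code); the dot matches any residue and is always last.",
 "classes": [
  {"symbol": "-", "name": "negative", "members": "DE"},
  {"symbol": "o", "name": "alcohol", "members": "ST"},
  {"symbol": "+", "name": "positive", "members": "HKR"},
  {"symbol": "l", "name": "aliphatic", "members": "ILV"},
  {"symbol": "u", "name": "tiny", "members": "AGS"},
  {"symbol": "a", "name": "aromatic", "members": "FHWY"},
  {"symbol": "c", "name": "charged", "members": "DEHKR"},
  {"symbol": "s", "name": "small", "members": "ACDGNPSTV"},
  {"symbol": "p", "name": "polar", "members": "CDEHKNQRST"},
  {"symbol": "t", "name": "turnlike", "members": "ACDEGHKNQRST"},
  {"symbol": "h", "name": "hydrophobic", "members": "ACFGHIKLMRTVWY"}
 ]
}
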