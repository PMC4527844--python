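{
 "_note": "Declarative per-set codon removals applied to the mammalian half-module coding sets before distance analysis: the fourth codon is removed from the N-half sets of modules 2 and 3, and codon 18 is removed from every C-half set except c5. Codon numbers are 1-based within the half-module.",
 "trims": {
  "n2": [4],
  "n3": [4],
  "c1": [18],
  "c2": [18],
  "c3": [18],
  "c4": [18],
  "c6": [18],
  "c7": [18]
 }
}
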