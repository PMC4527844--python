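{
 "_note": "Default spacing profile for the synthetic mammalian progranulin-like template (architecture p-g*-g-g-g-g-g-g). Entries give residue counts for the inter-cysteine regions of each half-module layout: N-half regions are [C1-C2, C2-C3C4, C3C4-C5C6]; C-half regions are [C5C6-C7C8, C7C8-C9C10, C9C10-C11, C11-C12]. The 10-cysteine (g*) module keeps the canonical layout but leaves the C2 and C11 slots as non-cysteine residues. Per-module overrides reproduce the mammalian half-module length arithmetic: after the declarative trims (remove codon 4 from n2/n3, codon 18 from every C-half set except c5) all eight N-half coding sets are 90 bases and all seven C-half sets are 75 bases.",
 "signal_len": 17,
 "linker_len": 6,
 "linker_split": 3,
 "tail_len": 3,
 "x_len": 60,
 "y_len": 8,
 "t_len": 4,
 "n_default": [6, 5, 7],
 "c_default": [8, 6, 4, 4],
 "paragranulin": [5, 5, 7],
 "n_breve_extra": [2, 2],
 "n_overrides": {"2": [7, 5, 7], "3": [7, 5, 7]},
 "c_overrides": {"5": [8, 6, 4, 3]}
}
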