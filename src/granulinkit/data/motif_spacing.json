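{
 "_note": "Default inclusive residue-count ranges for the seven inter-cysteine regions of the canonical 12-cysteine granulin motif (C1-C2, C2-C3C4, C3C4-C5C6, C5C6-C7C8, C7C8-C9C10, C9C10-C11, C11-C12). The motif literature prints no fixed spacing table; these ranges are a reviewable configuration asset chosen wide enough to accept every supported module form, with the length-variable regions being C1-C2, C4-C5 and C11-C12. All ranges are user-overridable.",
 "inter_cys_spacing": [[3, 9], [3, 8], [5, 13], [5, 12], [3, 10], [2, 8], [2, 9]],
 "extra_pair_spacing": [[1, 6], [1, 6]],
 "flank_n": 2,
 "flank_c": 2,
 "nhalf_tail": 4,
 "paragranulin_tail": 5
}
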