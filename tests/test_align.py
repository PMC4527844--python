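"""Anchored alignment: pinned cysteine columns, majority-rule gap placement."""

import numpy as np
import pytest

from granulinkit.align import (align_anchored, align_sequences, strip_columns,
                               unit_from_hit)
from granulinkit.errors import AlignmentError
from granulinkit.motif import MotifSpec, scan_protein
from granulinkit.synthetic import GeneratorConfig, build_template


def _module_seq(rng, r, absent=()):
    """One motif-bearing sequence with given inter-cysteine spacings."""
    aas = "ADEFGHIKLMNPQRSTVWY"
    groups = [["C1"], ["C2"], ["C3", "C4"], ["C5", "C6"],
              ["C7", "C8"], ["C9", "C10"], ["C11"], ["C12"]]
    out = ["".join(rng.choice(list(aas), 2))]
    for gi, grp in enumerate(groups):
        if gi:
            out.append("".join(rng.choice(list(aas), r[gi - 1])))
        for s in grp:
            out.append(rng.choice(list(aas)) if s in absent else "C")
    out.append("".join(rng.choice(list(aas), 2)))
    return "".join(out)


BASE_R = [6, 5, 7, 8, 6, 4, 4]


def test_identical_sequences_align_without_gaps(spec):
    rng = np.random.default_rng(0)
    seq = _module_seq(rng, BASE_R)
    aln = align_sequences([(f"s{i}", seq) for i in range(5)], spec)
    assert aln.width == len(seq)
    assert all(row == seq for _, row in aln.rows)
    assert not aln.region_gap_positions


def test_single_gap_placed_at_majority_column(spec):
    """Two C1-C2 spacings of 6 and 5: the shorter row gets one gap at the
    column where its residues best match the majority profile."""
    rng = np.random.default_rng(1)
    long_seq = _module_seq(rng, BASE_R)
    c1 = long_seq.index("C")
    region = long_seq[c1 + 1: c1 + 7]
    # delete the 3rd region residue: best (mismatch-free) gap column is known
    short_seq = long_seq[: c1 + 3] + long_seq[c1 + 4:]
    aln = align_sequences(
        [("a", long_seq), ("b", long_seq), ("c", short_seq)], spec)
    row_c = dict(aln.rows)["c"]
    start = aln.anchor_columns["C1"] + 1
    assert row_c[start: start + 6] == region[:2] + "-" + region[3:]
    assert aln.region_gap_positions["C1..C2"]["c"] == start + 2
    # all other columns match the majority rows
    assert dict(aln.rows)["a"] == long_seq
    assert aln.ungapped("c") == short_seq


def test_variant_rows_carry_placeholders_at_absent_anchors(spec):
    rng = np.random.default_rng(2)
    g_rows = [(f"g{i}", _module_seq(rng, BASE_R)) for i in range(3)]
    # 10-Cys form: C2 and C11 absent, one residue shorter in each region
    star = _module_seq(rng, [6, 5, 7, 8, 6, 4, 4], absent=("C2", "C11"))
    star = star.replace("C", "C", 1)
    units = []
    for lab, s in g_rows + [("star", star)]:
        hit = scan_protein(s, spec, sequence_id=lab)[0]
        units.append(unit_from_hit(lab, s, hit))
    aln = align_anchored(units, spec)
    row = dict(aln.rows)["star"]
    assert row[aln.anchor_columns["C2"]] == "-"
    assert row[aln.anchor_columns["C11"]] == "-"
    for lab, _ in g_rows:
        assert dict(aln.rows)[lab][aln.anchor_columns["C2"]] == "C"
    assert aln.ungapped("star") == star


def test_mixed_sides_rejected(spec, mammalian_template):
    gene, _ = mammalian_template
    prot = gene.protein
    hits = scan_protein(prot, spec)
    full = next(h for h in hits if h.variant == "g")
    n_unit = unit_from_hit("n", prot, full, side="N")
    c_unit = unit_from_hit("c", prot, full, side="C")
    with pytest.raises(AlignmentError, match="mixed sides"):
        align_anchored([n_unit, c_unit], spec)


def test_motif_free_sequence_rejected_by_label(spec):
    with pytest.raises(AlignmentError, match="nomotif"):
        align_sequences([("nomotif", "ACDEFGHIKLMNPQRST")], spec)


def test_strip_columns_removes_anchor_count(spec):
    rng = np.random.default_rng(3)
    seqs = [(f"s{i}", _module_seq(rng, BASE_R)) for i in range(4)]
    aln = align_sequences(seqs, spec)
    stripped = strip_columns(aln, drop_anchor_cys=True)
    assert stripped.width == aln.width - 12
    identity = strip_columns(aln, drop_anchor_cys=False)
    assert identity.width == aln.width

    n_aln = align_sequences(seqs, spec, side="N")
    assert strip_columns(n_aln).width == n_aln.width - 6


def test_row_permutation_only_permutes_output(spec):
    rng = np.random.default_rng(4)
    seqs = [(f"s{i}", _module_seq(rng, [5 + (i % 2), 5, 7, 8, 6, 4, 4]))
            for i in range(5)]
    a = align_sequences(seqs, spec)
    b = align_sequences(seqs[::-1], spec)
    assert dict(a.rows) == dict(b.rows)
    assert a.width == b.width


def test_ungap_recovers_every_input(spec):
    rng = np.random.default_rng(5)
    gene, _ = build_template(GeneratorConfig(architecture="sn-c"), rng)
    seqs = []
    for i in range(4):
        r = [6 - (i % 2), 5, 7, 8, 6, 4, 4 + (i % 3)]
        seqs.append((f"s{i}", _module_seq(rng, r)))
    aln = align_sequences(seqs, spec)
    for lab, seq in seqs:
        assert aln.ungapped(lab) == seq
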