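"""Motif detection: implant recovery, variant classification, half extraction."""

import numpy as np
import pytest

from granulinkit.errors import ConfigError, SequenceParseError
from granulinkit.gene import GeneModel
from granulinkit.motif import (MotifSpec, classify_variant, extract_half_modules,
                               scan_protein)
from granulinkit.synthetic import GeneratorConfig, build_template


def test_empty_sequence_has_no_motif(spec):
    assert scan_protein("", spec) == []


def test_invalid_residues_rejected(spec):
    with pytest.raises(SequenceParseError):
        scan_protein("ACDEB", spec)


def test_empty_spacing_range_is_config_error():
    with pytest.raises(ConfigError):
        MotifSpec.default(inter_cys_spacing=[(5, 3)] + [(3, 9)] * 6)


def test_single_implant_recovered_at_ground_truth_positions(spec):
    """A generated single-module gene yields exactly one hit whose cysteine
    coordinates match the implant."""
    rng = np.random.default_rng(7)
    gene, truth = build_template(GeneratorConfig(architecture="sn-c"), rng)
    hits = scan_protein(gene.protein, spec)
    assert len(hits) == 1
    truth_cys = sorted(c for u in truth.halves for c in u.cys)
    assert hits[0].cys_positions == truth_cys
    assert hits[0].variant == "g"


def test_tandem_implants_in_order_and_non_overlapping(spec):
    rng = np.random.default_rng(8)
    gene, _ = build_template(GeneratorConfig(architecture="sn-c-n-c"), rng)
    hits = scan_protein(gene.protein, spec)
    assert [h.variant for h in hits] == ["g", "g"]
    assert hits[0].span[1] <= hits[1].span[0]


@pytest.mark.parametrize("n,c,expected", [
    (6, 6, "g"),
    (5, 5, "g_star"),
    (4, 6, "g_dquote"),
    (8, 6, "g_breve"),
    (6, 0, "p"),
    (0, 6, "q"),
])
def test_variant_classification_from_half_counts(n, c, expected):
    assert classify_variant(n, c) == expected


def test_unknown_counts_reported_as_nonconforming():
    tag = classify_variant(3, 6)
    assert tag.startswith("nonconforming")
    assert "n=3" in tag and "c=6" in tag


def test_x_at_anchor_fails_strict_but_passes_lenient(mammalian_template):
    gene, truth = mammalian_template
    prot = gene.protein
    # knock one anchor cysteine of module 4 down to X
    target = next(u for u in truth.halves if u.set_name == "n4").cys[0]
    mutated = prot[:target] + "X" + prot[target + 1:]
    strict = scan_protein(mutated, MotifSpec.default())
    lenient = scan_protein(mutated, MotifSpec.default(lenient_x=True))
    intact = ["p", "g_star", "g", "g", "g", "g", "g", "g"]
    # strict mode: X never matches C, so module 4 cannot be a full module
    assert [h.variant for h in strict] != intact
    assert all(target not in h.cys_positions for h in strict)
    assert [h.variant for h in lenient] == intact
    assert any(target in h.cys_positions for h in lenient)


def test_half_extraction_partitions_module_span(mammalian_template, spec):
    gene, _ = mammalian_template
    prot = gene.protein
    for hit in scan_protein(prot, spec):
        n, c = extract_half_modules(hit, prot, spec=spec)
        if n is not None and c is not None:
            assert n.span[1] == c.span[0]
            assert (n.span[0], c.span[1]) == hit.span
            # junction: nhalf_tail residues beyond the second double Cys
            c6 = hit.slot_position("C6")
            assert n.span[1] == c6 + spec.nhalf_tail + 1
            assert n.span[0] == hit.cys_positions[0] - spec.flank_n
            assert c.span[1] == hit.cys_positions[-1] + spec.flank_c + 1


def test_paragranulin_keeps_five_tail_residues(mammalian_template, spec):
    gene, _ = mammalian_template
    prot = gene.protein
    p_hit = scan_protein(prot, spec)[0]
    assert p_hit.variant == "p"
    n, c = extract_half_modules(p_hit, prot, spec=spec)
    assert c is None
    c6 = p_hit.slot_position("C6")
    assert n.span[1] == c6 + spec.paragranulin_tail + 1


def test_exon_boundary_overrides_default_junction(spec):
    """A gene-model exon boundary 2 residues right of the default junction
    becomes the junction."""
    rng = np.random.default_rng(11)
    gene, truth = build_template(GeneratorConfig(architecture="sn-c"), rng)
    prot = gene.protein
    hit = scan_protein(prot, spec)[0]
    default_junction = hit.slot_position("C6") + spec.nhalf_tail + 1
    shifted = default_junction + 2
    boundaries = [b if b != default_junction else shifted
                  for b in truth.exon_boundaries]
    spans = []
    prev = 0
    for b in boundaries:
        spans.append((3 * prev, 3 * b))
        prev = b
    spans.append((3 * prev, len(gene.cds)))
    shifted_gene = GeneModel(gene.gene_id, gene.cds, spans)
    n, c = extract_half_modules(hit, prot, gene=shifted_gene, spec=spec)
    assert n.span[1] == shifted == c.span[0]
    assert len(n.coding_seq) == 3 * (n.span[1] - n.span[0])


@pytest.mark.parametrize("seed", range(6))
def test_hits_ordered_and_disjoint_on_random_architectures(seed, spec):
    from granulinkit.synthetic import random_architecture
    rng = np.random.default_rng(1000 + seed)
    arch = random_architecture(rng)
    gene, truth = build_template(GeneratorConfig(architecture=arch), rng)
    hits = scan_protein(gene.protein, spec)
    spans = [h.span for h in hits]
    assert spans == sorted(spans)
    for (a, b), (c, d) in zip(spans, spans[1:]):
        assert b <= c
    # every listed position really is a cysteine, strictly increasing
    for h in hits:
        assert h.cys_positions == sorted(h.cys_positions)
        assert all(gene.protein[p] == "C" for p in h.cys_positions)


def test_family_scan_recovers_ground_truth_everywhere(small_family, spec):
    """Round-trip: the scanner recovers the implanted module count and
    variant classes for every species of a synthetic family."""
    truth_variants = []
    for u in small_family.truth.halves:
        if u.kind == "nhalf":
            truth_variants.append(u.variant)
    for name, prot in small_family.proteins().items():
        hits = scan_protein(prot, spec, sequence_id=name)
        assert [h.variant for h in hits] == truth_variants, name
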