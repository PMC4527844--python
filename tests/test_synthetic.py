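"""Synthetic family generation: determinism, invariants, duplication."""

import numpy as np
import pytest

from granulinkit.architecture import annotate_gene, derive_architecture
from granulinkit.errors import ConfigError
from granulinkit.motif import scan_protein
from granulinkit.synthetic import (GeneratorConfig, build_template,
                                   evolve_family, jukes_cantor_pair,
                                   random_architecture, tandem_duplicate)


def test_same_seed_reproduces_template_different_seed_differs():
    cfg = GeneratorConfig()
    g1, _ = build_template(cfg, np.random.default_rng(5))
    g2, _ = build_template(cfg, np.random.default_rng(5))
    g3, _ = build_template(cfg, np.random.default_rng(6))
    assert g1.cds == g2.cds
    assert g1.cds != g3.cds
    # cysteine scaffold is seed-independent
    p1, p3 = g1.protein, g3.protein
    assert [i for i, c in enumerate(p1) if c == "C"] == \
        [i for i, c in enumerate(p3) if c == "C"]


def test_zero_rate_family_is_identical_to_template(mammalian_template):
    gene, truth = mammalian_template
    cfg = GeneratorConfig(n_species=4, global_rate=0.0)
    fam = evolve_family(gene, truth, cfg, np.random.default_rng(0))
    assert all(g.cds == gene.cds for g in fam.species.values())


def test_anchor_cysteines_invariant_across_species(small_family):
    truth_cys = [c for u in small_family.truth.halves for c in u.cys]
    for prot in small_family.proteins().values():
        assert all(prot[c] == "C" for c in truth_cys)


def test_no_new_cysteines_or_stops_introduced(small_family):
    truth_cys = {c for u in small_family.truth.halves for c in u.cys}
    for prot in small_family.proteins().values():
        assert {i for i, ch in enumerate(prot) if ch == "C"} == truth_cys
        assert "*" not in prot


def test_random_phylogeny_heights_scale(mammalian_template):
    gene, truth = mammalian_template
    cfg = GeneratorConfig(n_species=5, phylogeny="random", height=0.2)
    fam = evolve_family(gene, truth, cfg, np.random.default_rng(1))
    depths = fam.tree.calc_node_root_distances(return_leaf_distances_only=True)
    assert np.allclose(depths, 0.2, atol=1e-9)
    assert len(fam.species) == 5


def test_half_module_coding_lengths_match_spans(small_family):
    sets = small_family.half_set_alignments()
    for name, rows in sets.items():
        lengths = {len(s) for _, s in rows}
        assert len(lengths) == 1
        assert next(iter(lengths)) % 3 == 0


def test_tandem_duplicate_identical_copies(mammalian_template, spec):
    gene, truth = mammalian_template
    g2, t2 = tandem_duplicate(gene, truth, 4, 1, np.random.default_rng(2))
    hits = scan_protein(g2.protein, spec)
    assert len(hits) == len(truth.architecture.modules) + 1
    spans = t2.module_spans()
    prot = g2.protein
    assert prot[slice(*spans[4])] == prot[slice(*spans[5])]


def test_tandem_duplicate_ten_copies_yields_thirteen_modules(spec):
    rng = np.random.default_rng(3)
    gene, truth = build_template(
        GeneratorConfig(architecture="sn-c-n-c-n-c"), rng)
    assert truth.architecture.full_modules == 3
    g2, t2 = tandem_duplicate(gene, truth, 2, 10, rng)
    assert t2.architecture.full_modules == 13
    hits = scan_protein(g2.protein, spec)
    assert sum(1 for h in hits if h.variant == "g") == 13


def test_tandem_duplicate_extends_cn_chain(mammalian_template, spec):
    gene, truth = mammalian_template
    # module 5's N-half sits in a CN exon of the mammalian architecture
    g2, t2 = tandem_duplicate(gene, truth, 5, 1, np.random.default_rng(4))
    tok = annotate_gene(g2, scan_protein(g2.protein, spec))
    assert tok.serialize().count("cn") == truth.token_string.count("cn") + 1
    assert tok.serialize() == t2.token_string
    assert derive_architecture(tok).serialize() == t2.architecture.serialize()


def test_tandem_duplicate_near_identity_mutations(mammalian_template):
    gene, truth = mammalian_template
    g2, t2 = tandem_duplicate(gene, truth, 4, 1, np.random.default_rng(5),
                              mutations_per_copy=3)
    spans = t2.module_spans()
    prot = g2.protein
    orig, copy = prot[slice(*spans[4])], prot[slice(*spans[5])]
    assert sum(1 for a, b in zip(orig, copy) if a != b) == 3


def test_half_module_duplication_rejected(mammalian_template):
    gene, truth = mammalian_template
    with pytest.raises(ConfigError):
        tandem_duplicate(gene, truth, 99, 1, np.random.default_rng(6))


@pytest.mark.parametrize("seed", range(10))
def test_generator_round_trip_on_random_architectures(seed, spec):
    """Template -> scan -> annotate -> derive reproduces the configured
    architecture for randomly drawn supported architectures."""
    rng = np.random.default_rng(40_000 + seed)
    arch = random_architecture(rng)
    gene, truth = build_template(GeneratorConfig(architecture=arch), rng)
    tok = annotate_gene(gene, scan_protein(gene.protein, spec))
    assert derive_architecture(tok).serialize() == \
        truth.architecture.serialize(), arch


def test_jukes_cantor_pair_matches_expected_divergence():
    rng = np.random.default_rng(7)
    a, b = jukes_cantor_pair(50_000, 0.3, rng)
    observed = sum(1 for x, y in zip(a, b) if x != y) / len(a)
    expected = 0.75 * (1 - np.exp(-0.4))
    assert observed == pytest.approx(expected, abs=0.01)
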