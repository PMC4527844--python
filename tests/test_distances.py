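"""Distance estimators: oracles, invariances, statistical consistency."""

import numpy as np
import pytest

from granulinkit.distances import (DistanceMatrix, SubstitutionModel,
                                   jtt_ml_distance, load_mammalian_trims,
                                   logdet_distance, p_distance,
                                   pairwise_matrix, trim_codons,
                                   variability_summary)
from granulinkit.errors import DistanceError
from granulinkit.synthetic import jukes_cantor_pair, markov_chain_triple


def test_p_distance_arithmetic():
    assert p_distance("A" * 100, "A" * 100) == 0.0
    a = "A" * 63 + "C" * 7 + "-" * 30
    b = "A" * 70 + "-" * 30
    assert p_distance(a, b) == pytest.approx(0.1)
    with pytest.raises(DistanceError):
        p_distance("----", "AAAA")


def test_jtt_model_is_a_valid_rate_matrix():
    m = SubstitutionModel.jtt()
    assert np.allclose(m.Q.sum(axis=1), 0.0, atol=1e-12)
    assert m.pi.sum() == pytest.approx(1.0)
    # detailed balance and unit equilibrium rate
    assert np.allclose(m.pi[:, None] * m.Q, (m.pi[:, None] * m.Q).T, atol=1e-12)
    assert -np.sum(m.pi * np.diag(m.Q)) == pytest.approx(1.0)
    p = m.transition_matrix(0.7)
    assert np.allclose(p.sum(axis=1), 1.0)
    assert np.all(p > 0)


def test_jtt_distance_zero_for_identical():
    m = SubstitutionModel.jtt()
    a, _ = m.simulate_aligned_pair(200, 0.5, np.random.default_rng(0))
    assert jtt_ml_distance(a, a) == 0.0


def test_jtt_distance_dominates_p_distance():
    m = SubstitutionModel.jtt()
    rng = np.random.default_rng(1)
    for t in (0.1, 0.5, 1.2):
        a, b = m.simulate_aligned_pair(500, t, rng)
        assert jtt_ml_distance(a, b) >= p_distance(a, b)


def test_jtt_estimator_consistent_at_half_substitution_per_site():
    """Mean ML estimate over replicates falls within 3 standard errors of
    the simulated truth t=0.5."""
    m = SubstitutionModel.jtt()
    rng = np.random.default_rng(2024)
    ests = [jtt_ml_distance(*m.simulate_aligned_pair(10_000, 0.5, rng), m)
            for _ in range(100)]
    mean, se = np.mean(ests), np.std(ests, ddof=1) / 10.0
    assert abs(mean - 0.5) < 3 * se


def test_fast_matrix_agrees_with_scalar_optimizer():
    m = SubstitutionModel.jtt()
    rng = np.random.default_rng(3)
    # a star family: each taxon evolved from one ancestor, moderate distances
    anc = rng.choice(20, size=400, p=m.pi)
    seqs = []
    from granulinkit.distances import AA_ORDER
    for i in range(6):
        p = m.transition_matrix(0.05 + 0.1 * i)
        des = np.array([rng.choice(20, p=p[a] / p[a].sum()) for a in anc])
        seqs.append((f"a{i}", "".join(AA_ORDER[k] for k in des)))
    fast = pairwise_matrix(seqs, metric="jtt_ml", fast=True)
    slow = pairwise_matrix(seqs, metric="jtt_ml", fast=False)
    assert np.max(np.abs(fast.values - slow.values)) < 1e-2


def test_logdet_zero_for_identical_sequences():
    assert logdet_distance("ACGTACGTACGTTGCA", "ACGTACGTACGTTGCA") == \
        pytest.approx(0.0, abs=1e-12)


def test_logdet_invariant_to_simultaneous_base_relabeling():
    rng = np.random.default_rng(4)
    a, b = jukes_cantor_pair(2000, 0.4, rng)
    perm = str.maketrans("ACGT", "GTAC")
    assert logdet_distance(a, b) == pytest.approx(
        logdet_distance(a.translate(perm), b.translate(perm)), abs=1e-12)


def test_logdet_additive_along_markov_chain():
    rng = np.random.default_rng(5)
    d_ab = d_bc = d_ac = 0.0
    reps = 30
    for _ in range(reps):
        a, b, c = markov_chain_triple(5000, 0.15, 0.2, rng)
        d_ab += logdet_distance(a, b)
        d_bc += logdet_distance(b, c)
        d_ac += logdet_distance(a, c)
    assert d_ac / reps == pytest.approx((d_ab + d_bc) / reps, abs=0.02)


def test_logdet_flags_absent_base_class():
    # no G anywhere: marginals are singular, pseudocount rule applies
    d, status = logdet_distance("ACTACTACT", "ACTACTACT", return_status=True)
    assert status in ("pseudocount", "undefined")


def test_pairwise_matrix_bookkeeping():
    seqs = [("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")]
    dm = pairwise_matrix(seqs, metric="p")
    assert dm.n_pairs == 3
    assert np.all(dm.values == 0.0)
    two = pairwise_matrix(seqs[:2], metric="p")
    assert two.n_pairs == 1
    with pytest.raises(DistanceError):
        pairwise_matrix(seqs[:1], metric="p")


def test_variability_summary_hand_values():
    labels = ["x", "y", "z"]
    vals = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.3], [0.2, 0.3, 0.0]])
    dm = DistanceMatrix(labels, vals, "p")
    df = variability_summary([("s", dm)])
    assert df.loc["s", "n_pairs"] == 3
    assert df.loc["s", "mean"] == pytest.approx(0.2)
    assert df.loc["s", "sd"] == pytest.approx(np.std([0.1, 0.2, 0.3], ddof=1))
    zero = DistanceMatrix(labels, np.zeros((3, 3)), "p")
    dfz = variability_summary([("z", zero)])
    assert dfz.loc["z", "mean"] == 0.0 and dfz.loc["z", "sd"] == 0.0


def test_trim_codons_and_mammalian_table():
    seq = "".join(f"{chr(65 + i)}{chr(65 + i)}{chr(65 + i)}" for i in range(10))
    out = trim_codons(seq, [4])
    assert len(out) == 27 and "DDD" not in out
    trims = load_mammalian_trims()
    assert trims["n2"] == [4] and trims["c1"] == [18] and "c5" not in trims
    with pytest.raises(DistanceError):
        trim_codons("AAATTT", [5])
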