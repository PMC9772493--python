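"""Population-genetic estimators against hand-computed oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from hybridswarm.genotype_io import MISSING
from hybridswarm.popgen_stats import (
    EARTH_RADIUS_KM,
    DistanceMatrix,
    allele_frequencies,
    consensus_with_iupac,
    diversity,
    diversity_table,
    geographic_distances,
    mantel_ibd,
    nei_fst_two_pops,
    nei_pairwise_fst,
    p_distance,
    pooled_allele_counts,
)

from conftest import make_meta, make_table


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


def test_allele_frequencies_use_fully_called_genotypes_only():
    t = make_table([[(1, 1)], [(1, 2)], [(MISSING, 2)], [(MISSING, MISSING)]])
    meta = make_meta({s: "P" for s in t.samples})
    rec = allele_frequencies(t, meta).get("P", "loc1")
    # half-missing ind3 contributes nothing: 4 copies from ind1+ind2
    assert rec.n_obs == 4
    assert rec.freq(1) == pytest.approx(0.75)
    assert rec.freq(2) == pytest.approx(0.25)
    assert rec.expected_heterozygosity() == pytest.approx(2 * 0.75 * 0.25)


def test_pooled_allele_counts():
    t = make_table([[(1, 1)], [(1, 2)], [(MISSING, 2)]])
    counts = pooled_allele_counts(t, t.samples)
    assert counts["loc1"] == {1: 3, 2: 1}


# ---------------------------------------------------------------------------
# Diversity and Hardy-Weinberg
# ---------------------------------------------------------------------------


def test_hwe_chi2_extreme_heterozygote_deficit():
    # 50 AA + 50 aa: p = q = 0.5, expected 25/50/25, chi2 = 25+50+25 = 100
    pairs = [[(1, 1)]] * 50 + [[(2, 2)]] * 50
    t = make_table(pairs)
    meta = make_meta({s: "P" for s in t.samples})
    (rec,) = diversity(t, meta, "P")
    assert rec.hwe_method == "chi2"
    assert rec.He == pytest.approx(0.5)
    assert rec.Ho == pytest.approx(0.0)
    assert rec.hwe_p < 1e-20


def test_hwe_chi2_perfect_proportions():
    pairs = [[(1, 1)]] * 25 + [[(1, 2)]] * 50 + [[(2, 2)]] * 25
    t = make_table(pairs)
    meta = make_meta({s: "P" for s in t.samples})
    (rec,) = diversity(t, meta, "P")
    assert rec.hwe_p == pytest.approx(1.0)
    assert rec.Ho == pytest.approx(0.5)


def test_hwe_monte_carlo_on_sparse_table():
    # 8 individuals, 3 alleles: expected counts < 5 trigger the permutation test
    pairs = [[(1, 2)], [(1, 3)], [(2, 3)], [(1, 1)],
             [(2, 2)], [(3, 3)], [(1, 2)], [(1, 3)]]
    t = make_table(pairs)
    meta = make_meta({s: "P" for s in t.samples})
    (rec,) = diversity(t, meta, "P", seed=5)
    assert rec.hwe_method == "monte-carlo"
    assert 0.0 < rec.hwe_p <= 1.0
    (rec2,) = diversity(t, meta, "P", seed=5)
    assert rec2.hwe_p == rec.hwe_p  # seeded permutation test is reproducible


def test_hwe_monte_carlo_unremarkable_table_is_not_significant():
    # genotype counts close to HWE proportions must not be rejected
    pairs = [[(1, 1)]] * 3 + [[(1, 2)]] * 4 + [[(2, 2)]] * 2
    t = make_table(pairs)
    meta = make_meta({s: "P" for s in t.samples})
    (rec,) = diversity(t, meta, "P", seed=1)
    assert rec.hwe_method == "monte-carlo"
    assert rec.hwe_p > 0.2


def test_diversity_monomorphic_and_empty_loci():
    t = make_table([[(1, 1), (MISSING, MISSING)],
                    [(1, 1), (MISSING, MISSING)]])
    meta = make_meta({s: "P" for s in t.samples})
    recs = diversity(t, meta, "P")
    assert (recs[0].He, recs[0].Ho, recs[0].hwe_p) == (0.0, 0.0, 1.0)
    assert recs[0].hwe_method == "monomorphic"
    assert recs[1].hwe_method == "empty" and recs[1].n == 0
    df = diversity_table(recs)
    assert list(df["locus"]) == ["loc1", "loc2"]


# ---------------------------------------------------------------------------
# Nei pairwise FST
# ---------------------------------------------------------------------------

# Hand oracle: p1 = (0.9, 0.1), p2 = (0.2, 0.8), n1 = n2 = 10 diploids.
#   n_tilde = 10
#   Hs = (20/19) * (1 - ((.81+.01)+(.04+.64))/2) = (20/19) * 0.25 = 0.26315789
#   Ht = 1 - (0.55^2 + 0.45^2) = 0.495
#   FST = 1 - Hs/Ht = 0.46836790
HAND_FST = 1.0 - (20.0 / 19.0 * 0.25) / 0.495


def test_nei_fst_two_pops_hand_oracle():
    est = nei_fst_two_pops({1: 0.9, 2: 0.1}, {1: 0.2, 2: 0.8}, 10, 10)
    assert est == pytest.approx(HAND_FST, abs=1e-12)


def test_nei_fst_identical_populations_is_near_zero():
    # identical frequency vectors: Ht equals uncorrected Hs, so the
    # small-sample correction makes the estimate slightly negative --
    # negative estimates are reported, not clamped
    est = nei_fst_two_pops({1: 0.5, 2: 0.5}, {1: 0.5, 2: 0.5}, 10, 10)
    assert est < 0
    assert est == pytest.approx(1.0 - (20 / 19), abs=1e-12)


def test_nei_fst_fixed_difference():
    est = nei_fst_two_pops({1: 1.0}, {2: 1.0}, 10, 10)
    assert est == pytest.approx(1.0)


def test_nei_pairwise_fst_matches_hand_oracle(two_pop_table):
    table, meta = two_pop_table
    fst = nei_pairwise_fst(table, meta, n_boot=200, seed=3)
    # both loci are identical, so the multi-locus ratio equals the
    # single-locus hand value and the locus bootstrap is degenerate
    assert fst.value("P1", "P2") == pytest.approx(HAND_FST, abs=1e-12)
    assert fst.value("P2", "P1") == fst.value("P1", "P2")
    lo, hi = fst.ci("P1", "P2")
    assert lo == pytest.approx(HAND_FST) and hi == pytest.approx(HAND_FST)
    assert np.isnan(fst.value("P1", "P1"))


def test_nei_pairwise_fst_bootstrap_reproducible(two_pop_table):
    table, meta = two_pop_table
    a = nei_pairwise_fst(table, meta, n_boot=100, seed=11)
    b = nei_pairwise_fst(table, meta, n_boot=100, seed=11)
    assert a.ci("P1", "P2") == b.ci("P1", "P2")


def test_nei_pairwise_fst_input_validation(two_pop_table):
    table, meta = two_pop_table
    with pytest.raises(ValueError, match="two populations"):
        nei_pairwise_fst(table, meta, populations=["P1"])
    with pytest.raises(ValueError, match="two loci"):
        nei_pairwise_fst(table, meta, exclude_loci=["loc1"])


def test_fst_to_frame_layout(two_pop_table):
    table, meta = two_pop_table
    frame = nei_pairwise_fst(table, meta, n_boot=50, seed=0).to_frame()
    assert frame.loc["P2", "P1"] == f"{HAND_FST:.3f}"      # point below diagonal
    assert "-" in frame.loc["P1", "P2"]                    # CI above diagonal


# ---------------------------------------------------------------------------
# p-distance
# ---------------------------------------------------------------------------


def test_p_distance_simple_mismatch_counts():
    dm = p_distance([("a", "ACGT"), ("b", "ACGA"), ("c", "ACGT")])
    assert dm.value("a", "b") == pytest.approx(0.25)
    assert dm.value("a", "c") == 0.0
    assert dm.value("a", "a") == 0.0


def test_p_distance_matches_direct_mismatch_on_random_sequences():
    rng = np.random.default_rng(7)
    seqs = [(f"s{i}", "".join(rng.choice(list("ACGT"), size=60)))
            for i in range(5)]
    dm = p_distance(seqs)
    for (la, sa), (lb, sb) in itertools.combinations(seqs, 2):
        direct = sum(x != y for x, y in zip(sa, sb)) / 60
        assert dm.value(la, lb) == pytest.approx(direct)


def test_p_distance_pairwise_deletion_of_gaps_and_n():
    dm = p_distance([("a", "AC-TN"), ("b", "ACGTA")])
    # comparable columns: 1, 2, 4 -> zero mismatches over 3 sites
    assert dm.value("a", "b") == 0.0
    assert dm.comparable_sites[0, 1] == 3


def test_p_distance_ambiguity_expected_mismatch():
    # R = {A, G}: d(R, A) = 1 - 1/2; d(R, R) = 1 - 2/4; d(R, C) = 1
    assert p_distance([("a", "R"), ("b", "A")]).value("a", "b") == pytest.approx(0.5)
    assert p_distance([("a", "R"), ("b", "R")]).value("a", "b") == pytest.approx(0.5)
    assert p_distance([("a", "R"), ("b", "C")]).value("a", "b") == pytest.approx(1.0)
    # Y = {C, T} vs N-free comparisons stay within [0, 1]
    assert p_distance([("a", "Y"), ("b", "T")]).value("a", "b") == pytest.approx(0.5)


def test_p_distance_no_overlap_warns_and_yields_nan():
    with pytest.warns(UserWarning, match="comparable"):
        dm = p_distance([("a", "AC--"), ("b", "--GT")])
    assert np.isnan(dm.value("a", "b"))


def test_p_distance_input_validation():
    with pytest.raises(ValueError, match="length"):
        p_distance([("a", "ACGT"), ("b", "ACG")])
    with pytest.raises(ValueError, match="unknown"):
        p_distance([("a", "ACGZ"), ("b", "ACGT")])


def test_consensus_with_iupac():
    assert consensus_with_iupac("AAGT", "AAAT") == "AART"
    assert consensus_with_iupac("ACGT", "ACGT") == "ACGT"
    assert consensus_with_iupac("A-GT", "AAGT") == "ANGT"
    with pytest.raises(ValueError):
        consensus_with_iupac("ACG", "ACGT")


# ---------------------------------------------------------------------------
# Geography and Mantel
# ---------------------------------------------------------------------------


def test_haversine_known_distances():
    meta = make_meta({"a": "P", "b": "P", "c": "P"},
                     lat=[0.0, 0.0, 90.0], lon=[0.0, 180.0, 0.0])
    dm = geographic_distances(meta)
    half_circumference = np.pi * EARTH_RADIUS_KM
    assert dm.value("a", "b") == pytest.approx(half_circumference, rel=1e-9)
    assert dm.value("a", "c") == pytest.approx(half_circumference / 2, rel=1e-9)
    assert dm.value("a", "a") == 0.0


def test_geographic_distances_skip_missing_coordinates():
    meta = make_meta({"a": "P", "b": "P", "c": "P"},
                     lat=[0.0, np.nan, 1.0], lon=[0.0, 5.0, 1.0])
    with pytest.warns(UserWarning, match="coordinates"):
        dm = geographic_distances(meta)
    assert dm.labels == ["a", "c"]


def test_distance_matrix_helpers(tmp_path):
    d = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 3.0], [2.0, 3.0, 0.0]])
    dm = DistanceMatrix(["a", "b", "c"], d)
    assert dm.mean_between(["a"], ["b", "c"]) == pytest.approx(1.5)
    assert dm.submatrix(["c", "a"]).value("c", "a") == 2.0
    assert sorted(dm.lower_triangle()) == [1.0, 2.0, 3.0]
    dm.to_phylip(tmp_path / "d.phy")
    dm.to_nexus(tmp_path / "d.nex")
    assert (tmp_path / "d.phy").read_text().startswith("3\n")
    assert "TAXLABELS a b c" in (tmp_path / "d.nex").read_text()
    with pytest.raises(ValueError, match="symmetric"):
        DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))


def mantel_exact_p(x_mat, y_mat):
    """Exhaustive one-tailed Mantel p over all label permutations."""
    n = x_mat.shape[0]
    iu = np.tril_indices(n, k=-1)
    x = x_mat[iu]
    r_obs = np.corrcoef(x, y_mat[iu])[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        yp = y_mat[np.ix_(perm, perm)][iu]
        if np.corrcoef(x, yp)[0, 1] >= r_obs - 1e-12:
            count += 1
        total += 1
    return count / total


def test_mantel_matches_exhaustive_enumeration_on_four_labels():
    # 4 points on a line with all pairwise distances distinct
    pos = np.array([0.0, 1.0, 3.0, 7.0])
    geo_mat = np.abs(pos[:, None] - pos[None, :])
    gen_mat = geo_mat * 0.01          # perfectly correlated: r = 1
    labels = ["a", "b", "c", "d"]
    geo = DistanceMatrix(labels, geo_mat)
    gen = DistanceMatrix(labels, gen_mat)
    p_exact = mantel_exact_p(geo_mat, gen_mat)
    assert p_exact == pytest.approx(1 / 24)  # only the identity reaches r = 1
    r, p = mantel_ibd(geo, gen, n_perm=9999, seed=2)
    assert r == pytest.approx(1.0)
    # sampled permutation p converges on the exhaustive value
    assert abs(p - p_exact) < 0.01


def test_mantel_anticorrelated_distances_are_not_significant():
    pos = np.array([0.0, 1.0, 3.0, 7.0])
    geo_mat = np.abs(pos[:, None] - pos[None, :])
    gen_mat = geo_mat.max() + 1 - geo_mat
    np.fill_diagonal(gen_mat, 0.0)
    r, p = mantel_ibd(DistanceMatrix(list("abcd"), geo_mat),
                      DistanceMatrix(list("abcd"), gen_mat),
                      n_perm=999, seed=0)
    assert r < 0
    assert p > 0.9


def test_mantel_validation_and_degenerate_input():
    pos = np.array([0.0, 1.0, 3.0, 7.0])
    geo_mat = np.abs(pos[:, None] - pos[None, :])
    geo = DistanceMatrix(list("abcd"), geo_mat)
    gen_const = DistanceMatrix(list("abcd"), np.ones((4, 4)) - np.eye(4))
    with pytest.raises(ValueError, match="labels"):
        mantel_ibd(geo, DistanceMatrix(list("abce"), geo_mat))
    with pytest.raises(ValueError, match="permutations"):
        mantel_ibd(geo, geo, n_perm=50)
    r, p = mantel_ibd(geo, gen_const, n_perm=99)
    assert np.isnan(r) and np.isnan(p)


def test_mantel_null_false_positive_rate():
    """Independent random matrices must not produce an excess of small p."""
    rng = np.random.default_rng(31)
    labels = [f"s{i}" for i in range(10)]
    small = 0
    n_tests = 60
    for k in range(n_tests):
        a = rng.random((10, 2))
        b = rng.random((10, 2))
        da = np.linalg.norm(a[:, None] - a[None, :], axis=2)
        db = np.linalg.norm(b[:, None] - b[None, :], axis=2)
        _, p = mantel_ibd(DistanceMatrix(labels, da), DistanceMatrix(labels, db),
                          n_perm=99, seed=k)
        small += p <= 0.05
    # expected 3 of 60 at the null; allow generous binomial slack
    assert small <= 10
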