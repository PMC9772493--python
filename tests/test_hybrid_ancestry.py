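"""Diagnostic loci, ML hybrid index, ancestry categories, hypothesis test."""

from __future__ import annotations

import numpy as np
import pytest

from hybridswarm.genotype_io import MISSING
from hybridswarm.hybrid_ancestry import (
    AdmixtureDecision,
    DifferentialRecord,
    admixture_hypothesis_test,
    allele_frequency_differential,
    ancestry_categories,
    assign_parental_classes,
    category_tallies,
    hybrid_index_ml,
    hybrid_index_table,
    rare_allele_filter,
    select_diagnostic_loci,
)
from hybridswarm.popgen_stats import (
    AlleleFrequencyTable,
    DistanceMatrix,
    FrequencyRecord,
    allele_frequencies,
    nei_pairwise_fst,
)

from conftest import make_meta, make_table


def freq_table(records):
    return AlleleFrequencyTable(
        FrequencyRecord(pop, locus, freqs, n)
        for pop, locus, freqs, n in records
    )


# ---------------------------------------------------------------------------
# Rare-allele filter
# ---------------------------------------------------------------------------


def test_rare_allele_filter_masks_below_min_count():
    # loc1 counts: allele1 x5, allele2 x3; loc2: allele1 x6, allele2 x2
    t = make_table([
        [(1, 1), (1, 1)],
        [(1, 2), (1, 1)],
        [(1, 2), (1, 2)],
        [(2, 1), (1, 2)],
    ])
    filtered, dropped = rare_allele_filter(t, t.samples, min_count=3)
    # loc1: both alleles reach 3 copies -> untouched, not dropped
    assert filtered.genotype("ind2", "loc1") == (1, 2)
    assert "loc1" not in dropped
    # loc2: allele2 has 2 < 3 copies -> masked; only one allele survives
    assert filtered.genotype("ind3", "loc2") == (1, MISSING)
    assert dropped == ["loc2"]


def test_rare_allele_filter_boundary_is_strict():
    t = make_table([[(1, 2)], [(1, 2)], [(1, 2)]])  # 3 copies of each allele
    filtered, dropped = rare_allele_filter(t, t.samples, min_count=3)
    assert filtered == t.subset_samples(t.samples)  # count == min_count kept
    assert dropped == []
    with pytest.raises(ValueError):
        rare_allele_filter(t, t.samples, min_count=0)


# ---------------------------------------------------------------------------
# Allele-frequency differential
# ---------------------------------------------------------------------------


def test_differential_examples():
    freqs = freq_table([
        ("A", "fixed", {1: 1.0}, 20), ("B", "fixed", {2: 1.0}, 20),
        ("A", "same", {1: 0.5, 2: 0.5}, 20), ("B", "same", {1: 0.5, 2: 0.5}, 20),
        ("A", "diag", {1: 0.9, 2: 0.1}, 20), ("B", "diag", {1: 0.1, 2: 0.9}, 20),
        ("A", "nodata", {1: 1.0}, 20), ("B", "nodata", {}, 0),
    ])
    recs = {r.locus: r for r in allele_frequency_differential(freqs, "A", "B")}
    assert recs["fixed"].delta == pytest.approx(1.0)
    assert recs["fixed"].diagnostic
    assert recs["same"].delta == pytest.approx(0.0)
    assert recs["diag"].delta == pytest.approx(0.8)
    assert recs["diag"].diagnostic            # threshold 0.8 is inclusive
    assert not recs["nodata"].computable
    assert np.isnan(recs["nodata"].delta)


def test_differential_is_symmetric_and_label_invariant():
    rng = np.random.default_rng(2)
    for _ in range(20):
        k = rng.integers(2, 6)
        pa = rng.dirichlet(np.ones(k))
        pb = rng.dirichlet(np.ones(k))
        fa = {i + 1: float(v) for i, v in enumerate(pa)}
        fb = {i + 1: float(v) for i, v in enumerate(pb)}
        t1 = freq_table([("A", "l", fa, 20), ("B", "l", fb, 20)])
        t2 = freq_table([("A", "l", fb, 20), ("B", "l", fa, 20)])
        d1 = allele_frequency_differential(t1, "A", "B")[0].delta
        d2 = allele_frequency_differential(t2, "A", "B")[0].delta
        assert d1 == pytest.approx(d2)
        # relabeling allele codes leaves delta unchanged
        relabel = {i + 1: k - i for i in range(k)}
        t3 = freq_table([
            ("A", "l", {relabel[a]: v for a, v in fa.items()}, 20),
            ("B", "l", {relabel[a]: v for a, v in fb.items()}, 20),
        ])
        assert allele_frequency_differential(t3, "A", "B")[0].delta == pytest.approx(d1)


def test_select_diagnostic_loci_sorting_and_validation():
    diffs = [
        DifferentialRecord("x", 0.85, True),
        DifferentialRecord("y", 0.95, True),
        DifferentialRecord("z", 0.5, False),
        DifferentialRecord("w", float("nan"), False, computable=False),
    ]
    assert select_diagnostic_loci(diffs, 0.8) == ["y", "x"]
    assert select_diagnostic_loci(diffs, 0.9) == ["y"]
    with pytest.raises(ValueError):
        select_diagnostic_loci(diffs, 0.0)


def test_assign_parental_classes_majority_and_ties():
    freqs = freq_table([
        ("A", "l", {1: 0.9, 2: 0.05, 3: 0.05}, 20),
        ("B", "l", {1: 0.1, 2: 0.85, 3: 0.05}, 20),
    ])
    cm = assign_parental_classes(freqs, "A", "B", ["l"])
    assert cm["l"][1] == "A"
    assert cm["l"][2] == "B"
    assert 3 not in cm["l"]  # equal frequency: unassigned


# ---------------------------------------------------------------------------
# ML hybrid index
# ---------------------------------------------------------------------------


def fixed_freqs(loci):
    fa = {l: {1: 1.0, 2: 0.0} for l in loci}
    fb = {l: {1: 0.0, 2: 1.0} for l in loci}
    return fa, fb


def test_hybrid_index_closed_form_for_fixed_parents():
    """With fully fixed parental pools the MLE is (#A copies)/(2L)."""
    loci = [f"l{i}" for i in range(4)]
    fa, fb = fixed_freqs(loci)
    for k in range(9):
        row = np.array([[1, 1]] * (k // 2) + [[1, 2]] * (k % 2)
                       + [[2, 2]] * (4 - k // 2 - k % 2), dtype=np.int32)
        res = hybrid_index_ml(row, fa, fb, loci, loci, f"k{k}")
        assert res.h == pytest.approx(k / 8, abs=1e-5)
        assert res.ci_low - 1e-9 <= res.h <= res.ci_high + 1e-9
        assert res.n_loci_used == 4


def test_hybrid_index_grid_search_oracle():
    """MLE agrees with a fine grid search on 200 random instances."""
    rng = np.random.default_rng(99)
    grid = np.linspace(0.0, 1.0, 10_001)
    for _ in range(200):
        L = int(rng.integers(2, 9))
        loci = [f"l{i}" for i in range(L)]
        fa = {}
        fb = {}
        for l in loci:
            pa, pb = rng.random(2)
            fa[l] = {1: float(pa), 2: float(1 - pa)}
            fb[l] = {1: float(pb), 2: float(1 - pb)}
        row = np.stack([rng.integers(1, 3, size=L), rng.integers(1, 3, size=L)],
                       axis=1).astype(np.int32)
        res = hybrid_index_ml(row, fa, fb, loci, loci)
        pa_vec = np.array([fa[loci[j]][int(a)] for j in range(L) for a in row[j]])
        pb_vec = np.array([fb[loci[j]][int(a)] for j in range(L) for a in row[j]])
        ll = np.log(np.maximum(grid[:, None] * pa_vec
                               + (1 - grid[:, None]) * pb_vec, 1e-9)).sum(axis=1)
        h_grid = grid[int(ll.argmax())]
        assert abs(res.h - h_grid) < 1e-3


def test_hybrid_index_swap_symmetry():
    rng = np.random.default_rng(4)
    loci = [f"l{i}" for i in range(6)]
    fa = {l: {1: float(p), 2: float(1 - p)} for l, p in
          zip(loci, rng.random(6))}
    fb = {l: {1: float(p), 2: float(1 - p)} for l, p in
          zip(loci, rng.random(6))}
    row = rng.integers(1, 3, size=(6, 2)).astype(np.int32)
    h_ab = hybrid_index_ml(row, fa, fb, loci, loci).h
    h_ba = hybrid_index_ml(row, fb, fa, loci, loci).h
    assert h_ab == pytest.approx(1.0 - h_ba, abs=1e-5)


def test_hybrid_index_flat_likelihood_flag():
    loci = ["l0"]
    fa = {"l0": {1: 0.5, 2: 0.5}}
    res = hybrid_index_ml(np.array([[1, 2]], dtype=np.int32),
                          fa, fa, loci, loci)
    assert res.flat_likelihood
    assert res.h == 0.5
    assert (res.ci_low, res.ci_high) == (0.0, 1.0)


def test_hybrid_index_requires_usable_copies():
    loci = ["l0"]
    fa, fb = fixed_freqs(loci)
    with pytest.raises(ValueError, match="usable"):
        hybrid_index_ml(np.array([[MISSING, MISSING]], dtype=np.int32),
                        fa, fb, loci, loci, "empty")


def test_hybrid_index_counts_foreign_copies():
    loci = ["l0", "l1"]
    fa, fb = fixed_freqs(loci)
    row = np.array([[1, 2], [1, 7]], dtype=np.int32)  # allele 7 unseen
    res = hybrid_index_ml(row, fa, fb, loci, loci)
    assert res.n_foreign_copies == 1


def test_hybrid_index_table_f1_individuals():
    # F1s from fixed parents: every diagnostic locus heterozygous A/B
    loci = ["l0", "l1", "l2"]
    t = make_table([[(1, 2)] * 3, [(1, 2)] * 3], loci=loci)
    freqs = freq_table(
        [("A", l, {1: 1.0}, 20) for l in loci]
        + [("B", l, {2: 1.0}, 20) for l in loci]
    )
    results = hybrid_index_table(t, freqs, "A", "B", loci)
    for r in results:
        assert r.h == pytest.approx(0.5, abs=1e-4)
        assert r.het_interspecific == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# Ancestry categories
# ---------------------------------------------------------------------------


def test_ancestry_categories_and_tallies():
    loci = ["d1", "d2"]
    t = make_table(
        [[(1, 1), (1, 2)],
         [(2, 2), (MISSING, 1)],
         [(1, 2), (2, 2)]],
        loci=loci,
    )
    cm = {"d1": {1: "A", 2: "B"}, "d2": {1: "A", 2: "B"}}
    cats = ancestry_categories(t, loci, cm)
    assert cats.loc["ind1", "d1"] == "both-A"
    assert cats.loc["ind1", "d2"] == "mixed"
    assert cats.loc["ind2", "d1"] == "both-B"
    assert cats.loc["ind2", "d2"] == "missing"
    tallies = category_tallies(cats)
    assert tallies.loc["mixed", "d1"] == 1
    assert tallies.loc["missing", "d2"] == 1
    assert tallies["d1"].sum() == 3


# ---------------------------------------------------------------------------
# Admixture hypothesis test
# ---------------------------------------------------------------------------


def decision_from(d_hy_a, d_hy_b, d_a_b, f_hy_a, f_hy_b, f_a_b):
    """Build the decision from frozen study-style summary numbers."""
    labels = ["HY1", "HY2", "A1", "A2", "B1", "B2"]
    groups = {"HY": ["HY1", "HY2"], "A": ["A1", "A2"], "B": ["B1", "B2"]}
    between = {("HY", "A"): d_hy_a, ("HY", "B"): d_hy_b, ("A", "B"): d_a_b}
    d = np.zeros((6, 6))
    for i, li in enumerate(labels):
        for j, lj in enumerate(labels):
            gi, gj = li[:-1], lj[:-1]
            if gi != gj:
                key = (gi, gj) if (gi, gj) in between else (gj, gi)
                d[i, j] = between[key]
            elif i != j:
                d[i, j] = 0.001
    pdist = DistanceMatrix(labels, d)
    pops = ["HY", "A", "B"]
    point = np.full((3, 3), np.nan)
    for (x, y), v in {("HY", "A"): f_hy_a, ("HY", "B"): f_hy_b,
                      ("A", "B"): f_a_b}.items():
        i, j = pops.index(x), pops.index(y)
        point[i, j] = point[j, i] = v
    from hybridswarm.popgen_stats import FstMatrix

    fst = FstMatrix(pops, point, point, point, 0, [])
    meta = make_meta({s: s[:-1] for s in labels})
    return admixture_hypothesis_test(pdist, fst, meta, "HY", "A", "B")


def test_admixture_test_supports_hybrid_origin_on_study_style_numbers():
    dec = decision_from(0.0028, 0.0030, 0.0038, 0.215, 0.249, 0.273)
    assert dec.pdistance_criterion and dec.fst_criterion
    assert dec.verdict == "supports H2"
    assert "supports H2" in dec.report()


def test_admixture_test_rejects_when_fst_ordering_fails():
    dec = decision_from(0.0028, 0.0030, 0.0038, 0.30, 0.249, 0.273)
    assert dec.pdistance_criterion and not dec.fst_criterion
    assert dec.verdict == "does not support H2"


def test_admixture_test_inconclusive_when_population_absent():
    labels = ["A1", "A2", "B1", "B2"]
    pdist = DistanceMatrix(labels, np.ones((4, 4)) - np.eye(4))
    from hybridswarm.popgen_stats import FstMatrix

    fst = FstMatrix(["A", "B"], np.full((2, 2), 0.1),
                    np.full((2, 2), 0.1), np.full((2, 2), 0.1), 0, [])
    meta = make_meta({s: s[:-1] for s in labels})
    dec = admixture_hypothesis_test(pdist, fst, meta, "HY", "A", "B")
    assert dec.verdict == "inconclusive"


def test_admixture_test_on_real_estimators(two_pop_table):
    """End-to-end on computed estimators rather than frozen numbers: an
    intermediate population must sit between the parental pair."""
    table, meta = two_pop_table
    freqs = allele_frequencies(table, meta)
    diffs = allele_frequency_differential(freqs, "P1", "P2", threshold=0.5)
    assert [d.locus for d in diffs if d.diagnostic] == ["loc1", "loc2"]
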