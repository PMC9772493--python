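"""Diagnostic-locus ancestry analysis of a putative hybrid population.

Given two parental reference populations A and B, this module

* masks rare alleles (fewer than ``min_count`` copies pooled over the
  analysis set),
* measures the per-locus allele-frequency differential
  δ = ½ Σ_a |p_A(a) − p_B(a)| and selects species-diagnostic loci,
* estimates a per-individual maximum-likelihood hybrid index
  h ∈ [0, 1] (the proportion of ancestry drawn from population A) with a
  2-unit profile-log-likelihood interval, together with interspecific
  heterozygosity over diagnostic loci,
* classifies each (individual, diagnostic locus) genotype as both-A,
  both-B or mixed, and
* runs the formal comparison of the two competing hypotheses about the
  focal population: an isolated parental offshoot versus a hybrid swarm
  between the two parental species.

The hybrid-index likelihood for one individual is
``L(h) = Π_copies [h p_A(a) + (1−h) p_B(a)]`` over its non-missing allele
copies at the chosen loci; the log-likelihood is concave in h, so the
maximizer on [0, 1] is found by bounded scalar optimization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genotype_io import MISSING, GenotypeTable, SampleMetadata
from .popgen_stats import (
    AlleleFrequencyTable,
    DistanceMatrix,
    FstMatrix,
    allele_frequencies,
    pooled_allele_counts,
)

logger = logging.getLogger(__name__)

#: Floor on per-copy probabilities, so an allele absent from both parental
#: samples cannot send the log-likelihood to −inf.
PROB_FLOOR = 1e-9


# ---------------------------------------------------------------------------
# Rare-allele filter and frequency differentials
# ---------------------------------------------------------------------------


def rare_allele_filter(
    genotypes: GenotypeTable,
    analysis_samples: Sequence[str],
    min_count: int = 20,
) -> tuple[GenotypeTable, list[str]]:
    """Mask alleles carried fewer than ``min_count`` times (strictly) in the
    pooled analysis set; return the masked table restricted to the analysis
    samples and the list of loci left with fewer than two alleles (dropped
    from ancestry analysis downstream).
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    table = genotypes.subset_samples(analysis_samples)
    counts = pooled_allele_counts(table, analysis_samples)
    alleles = table.alleles.copy()
    dropped: list[str] = []
    for j, locus in enumerate(table.loci):
        rare = {a for a, c in counts[locus].items() if c < min_count}
        if rare:
            mask = np.isin(alleles[:, j, :], list(rare))
            alleles[:, j, :][mask] = MISSING
        surviving = {a for a, c in counts[locus].items() if c >= min_count}
        if len(surviving) < 2:
            dropped.append(locus)
            logger.info(
                "locus %s left with %d allele(s) after rare-allele filter; "
                "dropped from ancestry analysis", locus, len(surviving)
            )
    return GenotypeTable(list(table.samples), list(table.loci), alleles), dropped


@dataclass
class DifferentialRecord:
    """Allele-frequency differential between the parental populations."""

    locus: str
    delta: float
    diagnostic: bool = False
    computable: bool = True


def allele_frequency_differential(
    freqs: AlleleFrequencyTable,
    popA: str,
    popB: str,
    loci: Sequence[str] | None = None,
    threshold: float = 0.8,
) -> list[DifferentialRecord]:
    """δ = ½ Σ_alleles |p_A − p_B| per locus, with the diagnostic flag set at
    ``threshold``.  Loci absent (no data) in either population are flagged
    not computable."""
    if loci is None:
        loci = freqs.loci
    out: list[DifferentialRecord] = []
    for locus in loci:
        ra, rb = freqs.get(popA, locus), freqs.get(popB, locus)
        if ra.empty or rb.empty:
            out.append(DifferentialRecord(locus, float("nan"), False, False))
            continue
        alleles = set(ra.freqs) | set(rb.freqs)
        delta = 0.5 * sum(abs(ra.freq(a) - rb.freq(a)) for a in alleles)
        out.append(DifferentialRecord(locus, float(delta), delta >= threshold))
    return out


def select_diagnostic_loci(
    diffs: Sequence[DifferentialRecord], threshold: float = 0.8
) -> list[str]:
    """Loci with δ ≥ threshold, sorted by δ descending (ties by name)."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    chosen = [d for d in diffs if d.computable and d.delta >= threshold]
    chosen.sort(key=lambda d: (-d.delta, d.locus))
    if not chosen:
        logger.warning("no locus reaches the diagnostic differential threshold %.2f",
                       threshold)
    return [d.locus for d in chosen]


def assign_parental_classes(
    freqs: AlleleFrequencyTable,
    popA: str,
    popB: str,
    loci: Sequence[str],
) -> dict[str, dict[int, str]]:
    """Majority-frequency parental class per allele: 'A' where the allele is
    more frequent in population A, 'B' in B; equal frequencies leave the
    allele unassigned (absent from the map)."""
    class_map: dict[str, dict[int, str]] = {}
    for locus in loci:
        ra, rb = freqs.get(popA, locus), freqs.get(popB, locus)
        m: dict[int, str] = {}
        for a in set(ra.freqs) | set(rb.freqs):
            fa, fb = ra.freq(a), rb.freq(a)
            if fa > fb:
                m[a] = "A"
            elif fb > fa:
                m[a] = "B"
        class_map[locus] = m
    return class_map


# ---------------------------------------------------------------------------
# Maximum-likelihood hybrid index
# ---------------------------------------------------------------------------


@dataclass
class HybridIndexResult:
    """Per-individual ancestry proportion toward parental population A."""

    sample_id: str
    h: float
    ci_low: float
    ci_high: float
    het_interspecific: float
    n_loci_used: int
    loglik: float
    flat_likelihood: bool = False
    n_foreign_copies: int = 0  # copies absent from both parental samples


def _copy_probs(
    genotype_row: np.ndarray,
    loci: Sequence[str],
    all_loci: Sequence[str],
    freqsA: Mapping[str, Mapping[int, float]],
    freqsB: Mapping[str, Mapping[int, float]],
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Per-allele-copy (p_A, p_B) arrays over the usable loci."""
    pa_list: list[float] = []
    pb_list: list[float] = []
    n_loci_used = 0
    n_foreign = 0
    index = {l: i for i, l in enumerate(all_loci)}
    for locus in loci:
        j = index[locus]
        pair = genotype_row[j]
        fa, fb = freqsA.get(locus, {}), freqsB.get(locus, {})
        used = False
        for a in pair:
            if a == MISSING:
                continue
            pa, pb = fa.get(int(a), 0.0), fb.get(int(a), 0.0)
            if pa == 0.0 and pb == 0.0:
                n_foreign += 1
            pa_list.append(pa)
            pb_list.append(pb)
            used = True
        if used:
            n_loci_used += 1
    return np.array(pa_list), np.array(pb_list), n_loci_used, n_foreign


def hybrid_index_ml(
    genotype_row: np.ndarray,
    freqsA: Mapping[str, Mapping[int, float]],
    freqsB: Mapping[str, Mapping[int, float]],
    loci: Sequence[str],
    all_loci: Sequence[str],
    sample_id: str = "",
    class_map: Mapping[str, Mapping[int, str]] | None = None,
    tol: float = 1e-7,
) -> HybridIndexResult:
    """Maximum-likelihood hybrid index for one individual.

    ``genotype_row`` is the (n_loci, 2) allele-code slice for the
    individual over ``all_loci``; the likelihood uses only ``loci``.
    The profile-likelihood interval is the set of h whose log-likelihood is
    within 2 units of the maximum.  When p_A = p_B at every usable copy the
    likelihood is flat: h is reported as 0.5 and flagged.
    """
    pa, pb, n_used, n_foreign = _copy_probs(genotype_row, loci, all_loci, freqsA, freqsB)
    if pa.size == 0:
        raise ValueError(f"no usable allele copies for sample {sample_id!r}")

    def negll(h: float) -> float:
        return -float(np.log(np.maximum(h * pa + (1 - h) * pb, PROB_FLOOR)).sum())

    if np.allclose(pa, pb):
        het = _interspecific_het(genotype_row, loci, all_loci, class_map)
        return HybridIndexResult(sample_id, 0.5, 0.0, 1.0, het, n_used,
                                 -negll(0.5), flat_likelihood=True,
                                 n_foreign_copies=n_foreign)

    res = minimize_scalar(negll, bounds=(0.0, 1.0), method="bounded",
                          options={"xatol": tol})
    h_hat = float(res.x)
    # the bounded optimizer will not land exactly on the boundary; check ends
    candidates = [(negll(0.0), 0.0), (negll(1.0), 1.0), (float(res.fun), h_hat)]
    best = min(candidates, key=lambda t: (t[0], abs(t[1] - 0.5)))
    h_hat, ll_max = best[1], -best[0]

    target = -(ll_max - 2.0)  # negll value at the 2-unit drop

    def _bisect(lo: float, hi: float, increasing: bool) -> float:
        # find h with negll(h) = target on a monotone stretch
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if (negll(mid) > target) == increasing:
                hi = mid
            else:
                lo = mid
            if hi - lo < 1e-9:
                break
        return 0.5 * (lo + hi)

    ci_low = 0.0 if negll(0.0) <= target else _bisect(0.0, h_hat, increasing=False)
    ci_high = 1.0 if negll(1.0) <= target else _bisect(h_hat, 1.0, increasing=True)
    het = _interspecific_het(genotype_row, loci, all_loci, class_map)
    return HybridIndexResult(sample_id, h_hat, float(min(ci_low, h_hat)),
                             float(max(ci_high, h_hat)), het, n_used, ll_max,
                             n_foreign_copies=n_foreign)


def _interspecific_het(
    genotype_row: np.ndarray,
    loci: Sequence[str],
    all_loci: Sequence[str],
    class_map: Mapping[str, Mapping[int, str]] | None,
) -> float:
    """Proportion of classifiable diagnostic loci with one allele from each
    parental class."""
    if class_map is None:
        return float("nan")
    index = {l: i for i, l in enumerate(all_loci)}
    n_scored = 0
    n_mixed = 0
    for locus in loci:
        a, b = genotype_row[index[locus]]
        m = class_map.get(locus, {})
        ca, cb = m.get(int(a)), m.get(int(b))
        if a == MISSING or b == MISSING or ca is None or cb is None:
            continue
        n_scored += 1
        if ca != cb:
            n_mixed += 1
    return n_mixed / n_scored if n_scored else float("nan")


def hybrid_index_table(
    genotypes: GenotypeTable,
    freqs: AlleleFrequencyTable,
    popA: str,
    popB: str,
    loci: Sequence[str],
    samples: Sequence[str] | None = None,
    fixed_parents: bool = False,
) -> list[HybridIndexResult]:
    """Hybrid index for each sample in ``samples`` (default: all rows).

    ``fixed_parents=True`` rounds each parental frequency to its majority
    class (1 for the class-major population, 0 elsewhere), i.e. treats
    diagnostic alleles as fully fixed; the default uses the observed
    parental frequencies.
    """
    if samples is None:
        samples = genotypes.samples
    fa = {l: dict(freqs.get(popA, l).freqs) for l in loci}
    fb = {l: dict(freqs.get(popB, l).freqs) for l in loci}
    class_map = assign_parental_classes(freqs, popA, popB, loci)
    if fixed_parents:
        fa = {l: {a: (1.0 if class_map[l].get(a) == "A" else 0.0) for a in v}
              for l, v in fa.items()}
        fb = {l: {a: (1.0 if class_map[l].get(a) == "B" else 0.0) for a in v}
              for l, v in fb.items()}
    out = []
    for s in samples:
        row = genotypes.alleles[genotypes.sample_index(s)]
        out.append(
            hybrid_index_ml(row, fa, fb, loci, genotypes.loci, s, class_map)
        )
    return out


def hybrid_index_frame(results: Sequence[HybridIndexResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample": [r.sample_id for r in results],
            "h": [r.h for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "het_interspecific": [r.het_interspecific for r in results],
            "n_loci": [r.n_loci_used for r in results],
            "flat_likelihood": [r.flat_likelihood for r in results],
        }
    )


# ---------------------------------------------------------------------------
# Ancestry categories (diagnostic-locus genotype classes)
# ---------------------------------------------------------------------------

CATEGORIES = ("both-A", "both-B", "mixed", "missing")


def ancestry_categories(
    genotypes: GenotypeTable,
    diagnostic_loci: Sequence[str],
    class_map: Mapping[str, Mapping[int, str]],
) -> pd.DataFrame:
    """Per (sample, diagnostic locus) ancestry category.

    ``both-A``/``both-B`` when both alleles belong to one parental class,
    ``mixed`` when one allele comes from each, ``missing`` when either copy
    is missing or unassignable.
    """
    data: dict[str, list[str]] = {}
    for locus in diagnostic_loci:
        j = genotypes.locus_index(locus)
        col = []
        m = class_map.get(locus, {})
        for i in range(len(genotypes.samples)):
            a, b = genotypes.alleles[i, j]
            ca, cb = m.get(int(a)), m.get(int(b))
            if a == MISSING or b == MISSING or ca is None or cb is None:
                col.append("missing")
            elif ca == cb:
                col.append("both-A" if ca == "A" else "both-B")
            else:
                col.append("mixed")
        data[locus] = col
    return pd.DataFrame(data, index=genotypes.samples)


def category_tallies(categories: pd.DataFrame) -> pd.DataFrame:
    """Per-locus counts of each ancestry category."""
    return pd.DataFrame(
        {cat: (categories == cat).sum(axis=0) for cat in CATEGORIES}
    ).T


# ---------------------------------------------------------------------------
# Hypothesis comparison: isolated offshoot (H1) vs hybrid swarm (H2)
# ---------------------------------------------------------------------------


@dataclass
class AdmixtureDecision:
    """Outcome of the two-hypothesis comparison for the focal population."""

    d_hy_a: float
    d_hy_b: float
    d_a_b: float
    fst_hy_a: float
    fst_hy_b: float
    fst_a_b: float
    pdistance_criterion: bool
    fst_criterion: bool
    verdict: str
    ibd_within: Mapping[str, tuple[float, float]] | None = None
    ibd_between: tuple[float, float] | None = None
    reason: str = ""

    def report(self) -> str:
        lines = [
            "Hypothesis comparison: H1 isolated parental offshoot vs "
            "H2 hybrid swarm between the parental populations",
            f"  mean p-distance focal-A: {self.d_hy_a:.4f}",
            f"  mean p-distance focal-B: {self.d_hy_b:.4f}",
            f"  mean p-distance A-B:     {self.d_a_b:.4f}",
            f"  p-distance criterion (both focal distances < A-B): "
            f"{'satisfied' if self.pdistance_criterion else 'not satisfied'}",
            f"  FST focal-A: {self.fst_hy_a:.3f}",
            f"  FST focal-B: {self.fst_hy_b:.3f}",
            f"  FST A-B:     {self.fst_a_b:.3f}",
            f"  FST criterion (both focal FST < A-B): "
            f"{'satisfied' if self.fst_criterion else 'not satisfied'}",
        ]
        if self.ibd_within is not None:
            for pop, (r, p) in self.ibd_within.items():
                lines.append(f"  within-{pop} IBD Mantel r={r:.3f}, p={p:.4f}")
        if self.ibd_between is not None:
            r, p = self.ibd_between
            lines.append(f"  between-population IBD Mantel r={r:.3f}, p={p:.4f}")
        lines.append(f"  verdict: {self.verdict}")
        if self.reason:
            lines.append(f"  note: {self.reason}")
        return "\n".join(lines)


def admixture_hypothesis_test(
    pdist: DistanceMatrix,
    fst: FstMatrix,
    meta: SampleMetadata,
    pop_hybrid: str,
    popA: str,
    popB: str,
    ibd_within: Mapping[str, tuple[float, float]] | None = None,
    ibd_between: tuple[float, float] | None = None,
) -> AdmixtureDecision:
    """Evaluate the hybrid-swarm hypothesis for ``pop_hybrid``.

    Criterion (i): the focal population's mean between-population p-distance
    to each parental population is below the parental-parental distance.
    Criterion (ii): the same ordering holds for pairwise FST.  The verdict is
    "supports H2" iff both hold.  Supplied isolation-by-distance results are
    attached to the report (IBD within but not between populations argues
    against H1's pure-isolation explanation).
    """
    groups = {}
    for pop in (pop_hybrid, popA, popB):
        present = [s for s in meta.samples_in(pop) if s in pdist.labels]
        if not present:
            return AdmixtureDecision(
                *(float("nan"),) * 6, False, False,
                verdict="inconclusive",
                reason=f"population {pop!r} absent from the distance matrix",
            )
        groups[pop] = present
    try:
        fst_hy_a = fst.value(pop_hybrid, popA)
        fst_hy_b = fst.value(pop_hybrid, popB)
        fst_a_b = fst.value(popA, popB)
    except ValueError:
        return AdmixtureDecision(
            *(float("nan"),) * 6, False, False,
            verdict="inconclusive", reason="population missing from the FST matrix",
        )
    d_hy_a = pdist.mean_between(groups[pop_hybrid], groups[popA])
    d_hy_b = pdist.mean_between(groups[pop_hybrid], groups[popB])
    d_a_b = pdist.mean_between(groups[popA], groups[popB])
    crit_i = bool(d_hy_a < d_a_b and d_hy_b < d_a_b)
    crit_ii = bool(fst_hy_a < fst_a_b and fst_hy_b < fst_a_b)
    verdict = "supports H2" if (crit_i and crit_ii) else "does not support H2"
    return AdmixtureDecision(
        d_hy_a, d_hy_b, d_a_b, fst_hy_a, fst_hy_b, fst_a_b,
        crit_i, crit_ii, verdict, ibd_within, ibd_between,
    )
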