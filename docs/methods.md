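# Methods

This note pins down the statistical model, the exact estimator definitions
implemented (several classical statistics have multiple published variants),
the default parameters and the reasoning behind them, what the synthetic
study generator does and does not emulate, and the numerical choices that
make runs reproducible. Every quantitative claim here is either a formula
implemented in the package or a value computed by the test suite or the
acceptance script.

## 1. Data model

The unit of observation is an unordered diploid genotype: a pair of integer
allele codes per sample per locus. Alleles are coded per locus by collapsing
phased haplotype sequences to distinct-sequence codes in order of first
appearance (code 1 = first haplotype seen). `-1` is the missing code; a
genotype with either copy missing is treated as wholly missing by every
downstream statistic (half-calls carry phase ambiguity that the estimators
below cannot use safely). Pairs are stored in canonical sorted order with
missing codes last, so `(2,1)` and `(1,2)` are the same genotype.

Inputs:

* per-locus FASTA alignments with headers `sample|locus|phase` (phase 1/2),
  rejected if ragged, mislabelled, or containing duplicate sample/phase rows;
* a sample metadata table (`sample_id`, `population`, optional `lat`, `lon`,
  `mthap`, `substructure`);
* an ancestry-coefficient (Q) matrix whose rows must sum to 1 within 1e-3
  (then renormalized exactly).

Filters applied before analysis, in order:

1. **Phase confidence:** genotypes whose phasing posterior is strictly below
   0.95 are set to missing. 0.95 is the conventional phasing-certainty
   cutoff for Sanger-locus haplotype reconstruction.
2. **Representatives:** a sample represents its population if its largest Q
   value is strictly greater than 0.85, and it is not flagged for within-site
   substructure. 0.85 excludes recent migrants and strongly admixed
   individuals from *parental* reference panels while keeping panel sizes
   workable; the comparison is strict so the threshold itself is excluded.
3. **Rare alleles (ancestry analysis only):** alleles observed fewer than 20
   times across the analysis set are masked. With ~150 allele copies per
   locus, a count of 20 (~13%) removes alleles whose parental frequencies
   cannot be estimated well enough to contribute stable likelihood terms; a
   locus left with one allele after masking is dropped and logged.

## 2. Estimators

**Allele frequencies.** Computed from fully called genotypes only; the
number of observed copies `n_obs` excludes missing and half-missing
genotypes entirely.

**Heterozygosity and Hardy–Weinberg.** He = 1 − Σ p̂² (unbiased use is via
the F<sub>ST</sub> correction below, not here); Ho = fraction of called
heterozygotes. The HWE test is a chi-square over the k(k+1)/2 genotype
classes with k(k+1)/2 − k degrees of freedom. When any expected genotype
count is below 5 the chi-square distribution is unreliable, so the p-value
is instead computed by Monte Carlo: allele copies are permuted and re-paired
into genotypes, and p = (#{χ²_perm ≥ χ²_obs} + 1)/(B + 1) with B = 2000
permutations (vectorized). Monomorphic and empty loci are reported as such
rather than tested. The method used is recorded per locus
(`chi2` / `monte-carlo` / `monomorphic` / `empty`).

**Pairwise F<sub>ST</sub> (Nei, two populations).** Per locus,
Hs = (2ñ/(2ñ−1)) · (1 − mean over the two populations of Σ p̂²) with ñ the
harmonic mean sample size (small-sample correction), and
Ht = 1 − Σ p̄² with p̄ the unweighted mean frequency. The multilocus
estimate is 1 − (Σ_loci Hs)/(Σ_loci Ht) (ratio of sums, not mean of
ratios). Slightly negative estimates (identical populations) are *not*
clamped to zero — they are information about sampling noise. The 95% CI is
a percentile bootstrap over loci (default 2000 resamples); when all loci are
identical the interval collapses to the point estimate.

**p-distance.** Uncorrected proportion of mismatching sites with pairwise
deletion of gaps/unknowns. IUPAC ambiguity codes contribute their expected
mismatch 1 − |S_i ∩ S_j| / (|S_i|·|S_j|), where S is the set of bases a
code denotes — e.g. d(R,A) = 0.5, d(R,R) = 0.5, d(R,C) = 1. Pairs with no
comparable sites are NaN with a warning. Matrices export to PHYLIP and
NEXUS.

**Isolation by distance.** Mantel test of the p-distance (or F<sub>ST</sub>)
matrix against great-circle distance (haversine, Earth radius 6371 km).
One-tailed for positive correlation, p = (#{r_perm ≥ r_obs} + 1)/(B + 1),
default B = 9999. Constant matrices give r = NaN. For label sets small
enough to enumerate, an exact permutation p-value is available and the
sampled p is verified against it in the tests.

**Hybrid index.** For individual copies g₁…g_m over diagnostic loci,
ĥ = argmax Σ log( h·p_A(g) + (1−h)·p_B(g) ) on [0,1], with parental
frequencies p_A, p_B estimated from the representative panels. The
log-likelihood is concave, so a bounded scalar optimization finds the global
maximum; frequencies are floored at 1e-9 inside the likelihood to avoid
log(0) at the boundary. The reported interval is the 2-log-likelihood-unit
profile set (≈95% under the χ²₁ approximation). With fixed parental panels
(δ = 1 at all loci) the estimator reduces to the closed form
ĥ = k/(2L), k foreign copies among 2L copies — the test suite checks this
and cross-checks the optimizer against a 10001-point grid. A flat likelihood
(no informative copies) is flagged, reported as h = 0.5 with interval (0,1).
Interspecific heterozygosity is the fraction of diagnostic loci carrying one
copy of each parental class.

**Diagnostic loci.** δ = ½ Σ_a |p_A(a) − p_B(a)| per locus (symmetric and
invariant to allele relabelling); loci with δ ≥ 0.8 are diagnostic and
assigned a majority-rule parental class map (allele → the parent in which it
is more frequent; exact ties stay unassigned).

**Hypothesis decision.** H2 (hybrid swarm) is *supported* when both of
these hold, and *not supported* / *inconclusive* otherwise:

* mean between-population p-distance: focal–A and focal–B both strictly
  smaller than A–B;
* pairwise F<sub>ST</sub>: focal–A and focal–B both strictly smaller than
  A–B.

The decision object records both criteria separately with the numbers that
produced them; `inconclusive` is returned when a required population is
absent from either matrix.

## 3. Wright–Fisher simulator

Protocol:

1. **Generation 1 (F1):** each of N offspring takes copy 1 uniformly from
   the pool-A allele copies and copy 2 uniformly from pool-B, per locus.
   Generation 1 is therefore recorded as unfixed with class-A frequency
   exactly 0.5 in expectation (and exactly 0.5 realized when pools are
   monomorphic).
2. **Generations ≥ 2:** closed random mating, constant N, selfing allowed:
   each offspring copy is an independent uniform draw over the 2N parental
   copies. Per-locus class counts therefore follow the binomial
   Wright–Fisher chain; loci are independent.
3. **Fixation** of a locus is the first generation at which a single
   *parental class* (not necessarily a single allele) remains. Because the
   F1 is generation 1, a locus that fixes after g binomial transitions is
   recorded at generation g + 1.
4. Genotype snapshots are taken at configured checkpoints; trajectories can
   stop when all loci are fixed (`stop_when_fixed`) or run to the horizon,
   in which case unfixed loci are censored (NaN in summaries, horizon value
   in the acceptance script, which says so).

Verified against theory by the test suite (tolerances derived from the
sampling distributions *before* running, stated in the test docstrings):

* offspring counts at N = 50, p = 0.5 match binomial mean 50 and variance
  2Npq = 25;
* allele frequency is a martingale (3-standard-error envelope at several
  generations);
* expected heterozygosity decays as (1 − 1/2N) per generation (fitted slope
  within 5%);
* fixation probability equals the initial frequency (99% binomial CI at
  p₀ = 0.1 and 0.5);
* mean absorption time at p₀ = 0.5 matches the diffusion value 4N·ln 2
  within 10% at N = 100, and matches the *exact* absorbing-Markov-chain
  expectation (solved from (I − Q)t = 1) within 3 standard errors at
  2N = 4, including the +1 generation offset from the F1 convention.

Defaults: N = 100, 999 breeding generations (horizon 1000 with the F1),
4 replicates, checkpoints at generations 1, 2, 5, 10, 20, 50, 100, 200 and
500 (roughly log-spaced so both the early heterozygosity decay and the late
fixation tail are captured). N = 100 is a
plausible census size for an isolated pond population and makes the
diffusion timescale (mean absorption ≈ 277 generations at p₀ = 0.5)
comparable to the hypothesized swarm age; 4 replicates keep the default run
fast while the acceptance tests use their own replicate counts sized for
their tolerances.

## 4. Synthetic study generator

The generator builds a complete five-population study: parental pools A
(`SBE`, 16 samples) and B (`SQUen`, 18), a hybrid swarm (`SHY`, 26 sampled
from a census of N = 100 after 100 generations of closed mating), and two
outgroups (`SQUwn`, 7; `SQUes`, 8) drifted away from pool B. 87 samples
total including flagged substructure individuals. All numbers, class maps,
and per-individual true ancestry fractions h\* are written to `truth.json`
so the pipeline's estimates can be scored against ground truth.

What it emulates:

* **Diagnostic contrast by construction:** diagnostic loci (8 of 16) hit a
  requested frequency differential δ = 0.95 *exactly*, via disjoint
  high/low-frequency allele classes with mass m = (1+δ)/2; non-diagnostic
  loci share a common frequency spectrum.
* **Outgroup divergence by drift:** outgroup frequencies are obtained by
  binomial resampling of the source frequencies for T pseudo-generations,
  with T chosen by inverting the linearized relation F = 4T/(1+T) (capped
  at 0.97) so that the realized mean pairwise F<sub>ST</sub> against the
  source matches the requested target; the calibration is verified by a
  300-replicate test.
* **Mito-nuclear discordance:** the swarm carries parental-B mitochondrial
  haplotypes over an admixed nuclear genome; cytochrome-b haplotype clades
  are deeply divergent between parents (between-clade p-distance 0.06–0.12,
  within-clade < 0.02) as in species-level lineages.
* **Realistic missingness:** whole-genotype masking with a per-locus
  profile (one recently added locus at 25.3% missing, others 1.1–13.8%).
* **Geography with IBD:** sample coordinates are scattered within ±1° of
  per-population centers, with within-population spatial-genetic coupling
  so the Mantel tests have signal.
* **An ancestry-coefficient matrix** consistent with the true ancestry
  fractions, as a clustering program would estimate it.

What it does **not** emulate: sequencing or base-calling error, phasing
error (phase confidences are generated, not inferred), physical linkage or
recombination within loci (alleles are atomic codes), mutation during the
swarm's history, selection, migration into the closed swarm, or overlapping
generations. Consequently the generator is suitable for validating
estimator implementations and pipeline plumbing, not for fitting to any
real dataset.

Default swarm age is 100 generations: old enough that, at N = 100,
individual ancestry fractions have drifted visibly away from 0.5 and
interspecific heterozygosity has decayed below the F1 value of 1, which is
exactly the regime the hypothesis test is designed to distinguish from a
first-generation hybrid zone.

## 5. Numerical and reproducibility choices

* All randomness flows from one master seed through
  `numpy.random.SeedSequence.spawn`, so replicates, loci, and pipeline
  stages use independent, non-overlapping streams; derived integer seeds
  are reduced below 2³¹ for portability.
* The pipeline writes a `manifest.json` with per-output SHA-256 checksums;
  reruns with the same config are byte-identical (tested), and a failed
  stage is named in both the exception and the manifest.
* Bootstrap and permutation p-values use the +1/(B+1) convention so they
  are never exactly zero.
* Likelihood probabilities are floored at 1e-9; optimization is bounded on
  [0,1] (SciPy `minimize_scalar`), cross-checked against a dense grid in
  the tests.
* Monte Carlo HWE permutations are vectorized over replicates; the Mantel
  test permutes index arrays rather than copying matrices.

## 6. Limitations

* The F<sub>ST</sub> estimator is the specific Nei variant defined above;
  values are not directly comparable to Weir–Cockerham θ on the same data.
* The hybrid-index model treats loci and copies as independent
  (no linkage disequilibrium) and conditions on point estimates of parental
  frequencies; with few diagnostic loci the profile intervals are wide and
  the χ²₁ calibration is approximate.
* The HWE chi-square is anticonservative for sparse tables; the Monte Carlo
  fallback trades exactness for permutation noise (resolution 1/(B+1)).
* The simulator's neutrality and closed-population assumptions mean its
  fixation-time distribution is a null model: heavy right tails are
  expected (mean 4N·ln 2 with substantial variance), so observed
  segregation of diagnostic loci long after founding is compatible with
  neutrality and says little about selection or ongoing gene flow on its
  own.
* p-distance is uncorrected; for the shallow divergences generated here
  multiple-hit correction would change values negligibly, but the
  implementation should not be used for deep phylogenetic distances.
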