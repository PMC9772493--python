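"""Diversity, differentiation and distance statistics.

Implements the population-genetic layer of the analysis: per-locus allele
frequencies, expected/observed heterozygosity with a chi-square (or
Monte-Carlo) Hardy–Weinberg test, Nei pairwise FST with a locus bootstrap
for confidence intervals, uncorrected p-distance between aligned sequences
with IUPAC-ambiguity averaging, great-circle geographic distances, and the
Mantel permutation test used for isolation by distance.

Estimator conventions, pinned because the statistics literature offers
several variants:

* Nei FST per locus uses the sample-corrected within-population
  heterozygosity Hs = (2ñ/(2ñ−1)) (1 − mean_pop Σ p²) with ñ the harmonic
  mean diploid sample size, the plain total heterozygosity
  Ht = 1 − Σ p̄² over mean frequencies, and multi-locus combination by
  ratio of sums: FST = 1 − Σ_l Hs_l / Σ_l Ht_l.  Negative estimates are
  reported as computed, not clamped.
* The Hardy–Weinberg chi-square uses genotype categories with
  df = k(k+1)/2 − k; when any expected count is below 5 a seedable
  Monte-Carlo p-value (allele-copy permutation) replaces the asymptotic one.
* The Mantel test is one-tailed toward positive association with
  p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genotype_io import MISSING, GenotypeTable, SampleMetadata

EARTH_RADIUS_KM = 6371.0

#: IUPAC nucleotide codes mapped to their base sets.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"), "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"),
}
#: Characters treated as missing data (column excluded pairwise).
MISSING_CHARS = frozenset("N-?.")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class FrequencyRecord:
    """Allele relative frequencies at one locus in one population."""

    population: str
    locus: str
    freqs: dict[int, float]
    n_obs: int  # non-missing allele copies

    @property
    def empty(self) -> bool:
        return self.n_obs == 0

    def freq(self, allele: int) -> float:
        return self.freqs.get(allele, 0.0)

    def expected_heterozygosity(self) -> float:
        return 1.0 - sum(p * p for p in self.freqs.values())


class AlleleFrequencyTable:
    """Per (population, locus) allele-frequency records."""

    def __init__(self, records: Iterable[FrequencyRecord]):
        self._records: dict[tuple[str, str], FrequencyRecord] = {
            (r.population, r.locus): r for r in records
        }
        self.populations = sorted({p for p, _ in self._records})
        self.loci = sorted({l for _, l in self._records})

    def get(self, population: str, locus: str) -> FrequencyRecord:
        return self._records[(population, locus)]

    def records(self) -> list[FrequencyRecord]:
        return list(self._records.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"population": r.population, "locus": r.locus, "allele": a,
             "frequency": p, "n_obs": r.n_obs}
            for r in self._records.values()
            for a, p in sorted(r.freqs.items())
        ]
        return pd.DataFrame(rows)


def _locus_copies(genotypes: GenotypeTable, rows: Sequence[int], j: int) -> np.ndarray:
    """Non-missing allele copies for locus column j over the given sample
    rows.  Half-missing genotypes count as fully missing (no copy used)."""
    cells = genotypes.alleles[rows, j, :]
    complete = (cells != MISSING).all(axis=1)
    return cells[complete].ravel()


def allele_frequencies(
    genotypes: GenotypeTable,
    meta: SampleMetadata,
    populations: Sequence[str] | None = None,
) -> AlleleFrequencyTable:
    """Allele relative frequencies per population per locus, over fully
    called genotypes only."""
    if populations is None:
        populations = list(meta.populations)
    records: list[FrequencyRecord] = []
    sample_rows = {
        pop: [genotypes.sample_index(s) for s in meta.samples_in(pop)
              if s in genotypes.samples]
        for pop in populations
    }
    for pop in populations:
        rows = sample_rows[pop]
        for j, locus in enumerate(genotypes.loci):
            copies = _locus_copies(genotypes, rows, j)
            if copies.size == 0:
                records.append(FrequencyRecord(pop, locus, {}, 0))
                continue
            alleles, counts = np.unique(copies, return_counts=True)
            freqs = {int(a): float(c) / copies.size for a, c in zip(alleles, counts)}
            records.append(FrequencyRecord(pop, locus, freqs, int(copies.size)))
    return AlleleFrequencyTable(records)


def pooled_allele_counts(
    genotypes: GenotypeTable, samples: Sequence[str]
) -> dict[str, dict[int, int]]:
    """Raw allele-copy counts per locus pooled over ``samples``."""
    rows = [genotypes.sample_index(s) for s in samples]
    out: dict[str, dict[int, int]] = {}
    for j, locus in enumerate(genotypes.loci):
        copies = _locus_copies(genotypes, rows, j)
        alleles, counts = np.unique(copies, return_counts=True)
        out[locus] = {int(a): int(c) for a, c in zip(alleles, counts)}
    return out


# ---------------------------------------------------------------------------
# Diversity and Hardy–Weinberg
# ---------------------------------------------------------------------------


@dataclass
class DiversityRecord:
    """He, Ho and a Hardy–Weinberg p-value for one locus in one population."""

    locus: str
    He: float
    Ho: float
    hwe_p: float
    n: int
    hwe_method: str = "chi2"


def _hwe_chi2(genotype_counts: Mapping[tuple[int, int], int], n: int) -> tuple[float, float, bool]:
    """Chi-square statistic, asymptotic p, and a sparse-table flag."""
    copies: dict[int, int] = {}
    for (a, b), c in genotype_counts.items():
        copies[a] = copies.get(a, 0) + c
        copies[b] = copies.get(b, 0) + c
    alleles = sorted(copies)
    k = len(alleles)
    freqs = {a: copies[a] / (2 * n) for a in alleles}
    chi2 = 0.0
    sparse = False
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            exp = n * (freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b])
            obs = genotype_counts.get((a, b), 0)
            if exp < 5:
                sparse = True
            if exp > 0:
                chi2 += (obs - exp) ** 2 / exp
    df = k * (k + 1) // 2 - k
    p = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0
    return chi2, p, sparse


def _hwe_monte_carlo(
    cells: np.ndarray, chi2_obs: float, n_draws: int, rng: np.random.Generator
) -> float:
    """Permutation p-value: shuffle allele copies, re-pair, recompute chi2.

    Allele frequencies (hence HWE-expected counts) are invariant under the
    permutation, so only observed genotype-category counts change; all
    draws are scored in one vectorized pass.
    """
    n = cells.shape[0]
    alleles, copies = np.unique(cells.ravel(), return_inverse=True)
    k = alleles.size
    freqs = np.bincount(copies, minlength=k) / (2 * n)
    exp = n * np.outer(freqs, freqs)
    exp = np.where(np.eye(k, dtype=bool), exp, 2 * np.triu(exp, 1))
    exp = exp[np.triu_indices(k)]  # expected count per unordered category
    ncat = exp.size
    cat_index = np.zeros((k, k), dtype=np.int64)
    cat_index[np.triu_indices(k)] = np.arange(ncat)
    cat_index = np.maximum(cat_index, cat_index.T)

    # permute copies for all draws at once, pair consecutive copies
    keys = rng.random((n_draws, 2 * n))
    order = np.argsort(keys, axis=1)
    perm = copies[order].reshape(n_draws, n, 2)
    cats = cat_index[np.minimum(perm[..., 0], perm[..., 1]),
                     np.maximum(perm[..., 0], perm[..., 1])]
    offset = (np.arange(n_draws)[:, None]) * ncat
    flat = np.bincount((cats + offset).ravel(), minlength=n_draws * ncat)
    obs = flat.reshape(n_draws, ncat)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=1)
    exceed = int((chi2 >= chi2_obs - 1e-12).sum())
    return (exceed + 1) / (n_draws + 1)


def diversity(
    genotypes: GenotypeTable,
    meta: SampleMetadata,
    population: str,
    mc_draws: int = 10_000,
    seed: int | None = None,
) -> list[DiversityRecord]:
    """Per-locus expected/observed heterozygosity and HWE test for one
    population.  Monomorphic loci get He = Ho = 0 and p = 1."""
    rng = np.random.default_rng(seed)
    rows = [genotypes.sample_index(s) for s in meta.samples_in(population)
            if s in genotypes.samples]
    records: list[DiversityRecord] = []
    for j, locus in enumerate(genotypes.loci):
        cells = genotypes.alleles[rows, j, :]
        complete = cells[(cells != MISSING).all(axis=1)]
        n = complete.shape[0]
        if n == 0:
            records.append(DiversityRecord(locus, np.nan, np.nan, np.nan, 0, "empty"))
            continue
        copies = complete.ravel()
        _, counts = np.unique(copies, return_counts=True)
        freqs = counts / copies.size
        He = float(1.0 - (freqs**2).sum())
        Ho = float((complete[:, 0] != complete[:, 1]).mean())
        if len(counts) < 2:
            records.append(DiversityRecord(locus, 0.0, 0.0, 1.0, n, "monomorphic"))
            continue
        gcounts: dict[tuple[int, int], int] = {}
        for a, b in complete:
            key = (int(min(a, b)), int(max(a, b)))
            gcounts[key] = gcounts.get(key, 0) + 1
        chi2, p, sparse = _hwe_chi2(gcounts, n)
        method = "chi2"
        if sparse:
            p = _hwe_monte_carlo(complete, chi2, mc_draws, rng)
            method = "monte-carlo"
        records.append(DiversityRecord(locus, He, Ho, float(p), n, method))
    return records


def diversity_table(records: Sequence[DiversityRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "locus": [r.locus for r in records],
            "n": [r.n for r in records],
            "He": [r.He for r in records],
            "Ho": [r.Ho for r in records],
            "hwe_p": [r.hwe_p for r in records],
            "hwe_method": [r.hwe_method for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Nei pairwise FST with locus bootstrap
# ---------------------------------------------------------------------------


@dataclass
class FstMatrix:
    """Pairwise Nei FST point estimates with bootstrap percentile CIs."""

    populations: list[str]
    point: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_boot: int
    loci_used: list[str] = field(default_factory=list)

    def value(self, a: str, b: str) -> float:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.point[i, j])

    def ci(self, a: str, b: str) -> tuple[float, float]:
        i, j = self.populations.index(a), self.populations.index(b)
        return float(self.ci_low[i, j]), float(self.ci_high[i, j])

    def to_frame(self) -> pd.DataFrame:
        """Lower triangle: point estimates; upper triangle: '<lo>-<hi>' CIs."""
        n = len(self.populations)
        cells = [["" for _ in range(n)] for _ in range(n)]
        for i in range(n):
            for j in range(n):
                if i > j:
                    cells[i][j] = f"{self.point[i, j]:.3f}"
                elif i < j:
                    cells[i][j] = f"{self.ci_low[i, j]:.3f}-{self.ci_high[i, j]:.3f}"
        return pd.DataFrame(cells, index=self.populations, columns=self.populations)


def _pair_locus_components(
    freqs: "AlleleFrequencyTable", popA: str, popB: str, loci: Sequence[str]
) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus (Hs, Ht) for one population pair under the pinned Nei
    estimator; loci where either population has no data are dropped."""
    hs_list, ht_list = [], []
    for locus in loci:
        ra, rb = freqs.get(popA, locus), freqs.get(popB, locus)
        if ra.empty or rb.empty:
            continue
        na, nb = ra.n_obs / 2.0, rb.n_obs / 2.0  # diploid sample sizes
        n_tilde = 2.0 / (1.0 / na + 1.0 / nb)
        alleles = set(ra.freqs) | set(rb.freqs)
        pa = np.array([ra.freq(a) for a in sorted(alleles)])
        pb = np.array([rb.freq(a) for a in sorted(alleles)])
        hs_raw = 1.0 - 0.5 * ((pa**2).sum() + (pb**2).sum())
        hs = (2.0 * n_tilde / (2.0 * n_tilde - 1.0)) * hs_raw
        pbar = 0.5 * (pa + pb)
        ht = 1.0 - (pbar**2).sum()
        hs_list.append(hs)
        ht_list.append(ht)
    return np.array(hs_list), np.array(ht_list)


def _combine(hs: np.ndarray, ht: np.ndarray) -> float:
    tot = ht.sum()
    if tot <= 0:
        return 0.0
    return float(1.0 - hs.sum() / tot)


def nei_pairwise_fst(
    genotypes: GenotypeTable,
    meta: SampleMetadata,
    populations: Sequence[str] | None = None,
    exclude_loci: Iterable[str] = (),
    n_boot: int = 1000,
    seed: int | None = None,
) -> FstMatrix:
    """Nei pairwise FST over all population pairs, with a percentile 95% CI
    from resampling loci with replacement."""
    if populations is None:
        populations = list(meta.populations)
    populations = list(populations)
    if len(populations) < 2:
        raise ValueError("need at least two populations")
    loci = [l for l in genotypes.loci if l not in set(exclude_loci)]
    if len(loci) < 2:
        raise ValueError("need at least two loci after exclusion")
    freqs = allele_frequencies(genotypes, meta, populations)
    n = len(populations)
    point = np.zeros((n, n))
    lo = np.zeros((n, n))
    hi = np.zeros((n, n))
    rng = np.random.default_rng(seed)
    for i in range(n):
        for j in range(i + 1, n):
            hs, ht = _pair_locus_components(freqs, populations[i], populations[j], loci)
            if hs.size == 0:
                raise ValueError(
                    f"populations {populations[i]!r} and {populations[j]!r} share "
                    "no genotyped locus"
                )
            est = _combine(hs, ht)
            idx = rng.integers(0, hs.size, size=(n_boot, hs.size))
            boots = np.array([_combine(hs[b], ht[b]) for b in idx])
            point[i, j] = point[j, i] = est
            lo[i, j] = lo[j, i] = np.percentile(boots, 2.5)
            hi[i, j] = hi[j, i] = np.percentile(boots, 97.5)
    np.fill_diagonal(point, np.nan)
    np.fill_diagonal(lo, np.nan)
    np.fill_diagonal(hi, np.nan)
    return FstMatrix(populations, point, lo, hi, n_boot, loci)


def nei_fst_two_pops(
    pa: Mapping[int, float], pb: Mapping[int, float], na: int, nb: int
) -> float:
    """Single-locus pinned Nei FST from explicit frequency vectors and
    diploid sample sizes (convenience for oracles and small examples)."""
    alleles = sorted(set(pa) | set(pb))
    va = np.array([pa.get(a, 0.0) for a in alleles])
    vb = np.array([pb.get(a, 0.0) for a in alleles])
    n_tilde = 2.0 / (1.0 / na + 1.0 / nb)
    hs = (2 * n_tilde / (2 * n_tilde - 1)) * (1 - 0.5 * ((va**2).sum() + (vb**2).sum()))
    ht = float(1 - ((0.5 * (va + vb)) ** 2).sum())
    return float(1.0 - hs / ht) if ht > 0 else 0.0


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with per-pair comparable-site counts."""

    labels: list[str]
    d: np.ndarray
    comparable_sites: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")

    def value(self, a: str, b: str) -> float:
        return float(self.d[self.labels.index(a), self.labels.index(b)])

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        comp = None
        if self.comparable_sites is not None:
            comp = self.comparable_sites[np.ix_(idx, idx)]
        return DistanceMatrix(list(labels), self.d[np.ix_(idx, idx)], comp)

    def mean_between(self, group_a: Sequence[str], group_b: Sequence[str]) -> float:
        ia = [self.labels.index(l) for l in group_a]
        ib = [self.labels.index(l) for l in group_b]
        vals = self.d[np.ix_(ia, ib)]
        return float(np.nanmean(vals))

    def lower_triangle(self) -> np.ndarray:
        iu = np.tril_indices(len(self.labels), k=-1)
        return self.d[iu]

    def to_phylip(self, path: str | Path) -> None:
        lines = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.d):
            lines.append(lab.ljust(12) + " ".join(f"{v:.6f}" for v in row))
        Path(path).write_text("\n".join(lines) + "\n")

    def to_nexus(self, path: str | Path) -> None:
        n = len(self.labels)
        lines = [
            "#NEXUS", "BEGIN TAXA;", f"  DIMENSIONS NTAX={n};",
            "  TAXLABELS " + " ".join(self.labels) + ";", "END;",
            "BEGIN DISTANCES;", "  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;", "  MATRIX",
        ]
        for lab, row in zip(self.labels, self.d):
            lines.append("    " + lab + " " + " ".join(f"{v:.6f}" for v in row))
        lines += ["  ;", "END;"]
        Path(path).write_text("\n".join(lines) + "\n")


def _ambiguity_weight_matrix(alphabet: str) -> np.ndarray:
    """W[i, j] = expected mismatch between IUPAC codes i and j:
    1 − |S_i ∩ S_j| / (|S_i| · |S_j|)."""
    n = len(alphabet)
    W = np.ones((n, n))
    for i, a in enumerate(alphabet):
        for j, b in enumerate(alphabet):
            sa, sb = IUPAC_SETS[a], IUPAC_SETS[b]
            W[i, j] = 1.0 - len(sa & sb) / (len(sa) * len(sb))
    return W


_ALPHABET = "ACGTURYSWKMBDHV"
_WEIGHTS = _ambiguity_weight_matrix(_ALPHABET)
_CHAR_INDEX = {c: i for i, c in enumerate(_ALPHABET)}


def p_distance(seqs: Sequence[tuple[str, str]]) -> DistanceMatrix:
    """Uncorrected p-distance over equal-length aligned sequences.

    Columns where either sequence carries a gap/N are excluded pairwise;
    IUPAC ambiguity codes contribute their expected mismatch under uniform
    base assignment ("average states"), and the sum is normalized by the
    number of comparable columns.  A pair with no comparable column gets a
    NaN distance and a warning.
    """
    labels = [lab for lab, _ in seqs]
    raw = [s.upper() for _, s in seqs]
    L = len(raw[0]) if raw else 0
    for lab, s in zip(labels, raw):
        if len(s) != L:
            raise ValueError(f"sequence {lab!r} length {len(s)} != {L}")
    n = len(raw)
    # encode: 0..len(alphabet)-1 for bases, -1 for missing chars
    enc = np.full((n, L), -1, dtype=np.int8)
    for i, s in enumerate(raw):
        for j, c in enumerate(s):
            if c in _CHAR_INDEX:
                enc[i, j] = _CHAR_INDEX[c]
            elif c not in MISSING_CHARS:
                raise ValueError(f"unknown nucleotide character {c!r} in {labels[i]!r}")
    d = np.zeros((n, n))
    comp = np.zeros((n, n), dtype=int)
    for i in range(n):
        comp[i, i] = int((enc[i] >= 0).sum())
        for j in range(i + 1, n):
            ok = (enc[i] >= 0) & (enc[j] >= 0)
            m = int(ok.sum())
            comp[i, j] = comp[j, i] = m
            if m == 0:
                warnings.warn(
                    f"no comparable sites between {labels[i]!r} and {labels[j]!r}"
                )
                d[i, j] = d[j, i] = np.nan
                continue
            w = _WEIGHTS[enc[i][ok], enc[j][ok]].sum()
            d[i, j] = d[j, i] = w / m
    return DistanceMatrix(labels, d, comp)


def consensus_with_iupac(seq1: str, seq2: str) -> str:
    """Collapse two phased haplotypes into one unphased sequence, writing
    IUPAC ambiguity codes at heterozygous columns (as direct Sanger reads
    of a diploid would show)."""
    if len(seq1) != len(seq2):
        raise ValueError("haplotypes must be aligned to equal length")
    rev = {frozenset(v): k for k, v in IUPAC_SETS.items() if k != "U"}
    out = []
    for a, b in zip(seq1.upper(), seq2.upper()):
        if a == b:
            out.append(a)
        elif a in MISSING_CHARS or b in MISSING_CHARS:
            out.append("N")
        else:
            union = IUPAC_SETS[a] | IUPAC_SETS[b]
            out.append(rev.get(frozenset(union), "N"))
    return "".join(out)


def geographic_distances(
    meta: SampleMetadata, samples: Sequence[str] | None = None
) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between sample localities.
    Samples without coordinates are excluded with a warning."""
    if samples is None:
        samples = meta.samples
    kept, lats, lons = [], [], []
    for s in samples:
        lat, lon = meta.table.loc[s, "lat"], meta.table.loc[s, "lon"]
        if pd.isna(lat) or pd.isna(lon):
            warnings.warn(f"sample {s!r} has no coordinates; excluded from geography")
            continue
        kept.append(s)
        lats.append(float(lat))
        lons.append(float(lon))
    phi = np.radians(np.array(lats))
    lam = np.radians(np.array(lons))
    dphi = phi[:, None] - phi[None, :]
    dlam = lam[:, None] - lam[None, :]
    a = np.sin(dphi / 2) ** 2 + np.cos(phi)[:, None] * np.cos(phi)[None, :] * np.sin(dlam / 2) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2  # enforce exact symmetry against float noise
    return DistanceMatrix(kept, d)


# ---------------------------------------------------------------------------
# Mantel isolation-by-distance test
# ---------------------------------------------------------------------------


def mantel_ibd(
    geo: DistanceMatrix,
    gen: DistanceMatrix,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """One-tailed Mantel test of isolation by distance.

    Returns (r, p) where r is the Pearson correlation between the strictly
    lower triangles and p = (#{r_perm ≥ r_obs} + 1)/(n_perm + 1) under label
    permutations of the genetic matrix.  A constant matrix yields r = NaN.
    """
    if geo.labels != gen.labels:
        raise ValueError("distance matrices must share labels in the same order")
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    x = geo.lower_triangle()
    y = gen.lower_triangle()
    if np.nanstd(x) == 0 or np.nanstd(y) == 0:
        return float("nan"), float("nan")
    r_obs = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    n = len(geo.labels)
    iu = np.tril_indices(n, k=-1)
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        yp = gen.d[np.ix_(perm, perm)][iu]
        r_perm = float(np.corrcoef(x, yp)[0, 1])
        if r_perm >= r_obs - 1e-12:
            exceed += 1
    return r_obs, (exceed + 1) / (n_perm + 1)
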