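"""Synthetic study generator.

Produces inputs with the statistical structure the analysis assumes, so the
whole pipeline is testable without external downloads: two differentiated
parental populations nearly fixed for alternative allele classes at a set
of diagnostic loci, a hybrid swarm of known age bred from them by the
Wright–Fisher simulator (with per-individual true ancestry tracked), a
strongly drifted "island" population, mild within-species structure,
missing data with a realistic per-locus profile, geography with
within-population isolation by distance, an emulated ancestry-coefficient
matrix, and mitochondrial haplotypes exhibiting mito-nuclear discordance
(the hybrid population carries parental-B mitochondrial haplotypes).

Default design values mirror the study system: 16 nuclear amplicons with
2–9 alleles, eight diagnostic loci at allele-frequency differential
δ ≥ 0.95, representative sample sizes 16/18/26/7/8 for the two parental
populations, the hybrid swarm and the two outgroup populations, ~7%
missing genotypes on average (one locus much higher), plus seven low-Q
early-admixture individuals and five substructure individuals that the
representative filter removes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genotype_io import (
    MISSING,
    GenotypeTable,
    QMatrix,
    SampleMetadata,
    write_qmatrix,
)
from . import wf_simulator

#: Default amplicon panel (name -> aligned clean length in bp).
DEFAULT_LOCI: dict[str, int] = {
    "17367": 589, "AKR": 423, "DNAH3": 625, "FSHR": 652, "GHR": 605,
    "NB14108": 640, "PLXNA2": 688, "PRLR": 445, "TAR": 491, "TB29": 490,
    "TB54": 584, "TB62": 580, "TB73_new": 376, "TB75": 460, "TB81": 618,
    "VIM_new": 523,
}
#: Default diagnostic subset (nearly fixed differences between parents).
DEFAULT_DIAGNOSTIC = ("17367", "DNAH3", "FSHR", "GHR", "PRLR", "TAR", "TB62", "TB81")

DEFAULT_POP_SIZES = {"SBE": 16, "SQUen": 18, "SHY": 26, "SQUwn": 7, "SQUes": 8}

#: Arbitrary population centres (decimal degrees) for synthetic geography.
DEFAULT_CENTERS = {
    "SBE": (24.2, 114.0), "SQUen": (21.6, 107.9), "SHY": (22.4, 110.5),
    "SQUwn": (21.9, 106.2), "SQUes": (19.3, 110.0),
}

CYTB_LENGTH = 1144


@dataclass
class SyntheticDesign:
    """Knobs of the synthetic study; defaults emulate the real design."""

    n_loci: int = 16
    alleles_per_locus: tuple[int, int] = (2, 9)
    n_diagnostic: int = 8
    delta_target: float = 0.95
    pop_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_POP_SIZES))
    missing_rate: float = 0.071
    per_locus_missing: dict[str, float] | None = None
    swarm_age: int = 100          # generations since the F1 for the hybrid swarm
    swarm_N: int = 100            # swarm census size during breeding
    fst_island: float = 0.45      # target drift of the isolated population
    fst_outgroup: float = 0.15    # mild drift of the second outgroup
    n_low_q: dict[str, int] = field(
        default_factory=lambda: {"SQUen": 4, "SQUwn": 2, "SHY": 1}
    )
    n_substructure: dict[str, int] = field(
        default_factory=lambda: {"SQUen": 2, "SQUwn": 3}
    )
    ibd_strength: float = 3.0
    seed: int | None = None
    locus_names: tuple[str, ...] = tuple(DEFAULT_LOCI)
    diagnostic_names: tuple[str, ...] = DEFAULT_DIAGNOSTIC
    pop_a: str = "SBE"            # parental population A (nuclear)
    pop_b: str = "SQUen"          # parental population B (mtDNA donor of the swarm)
    pop_hybrid: str = "SHY"

    def __post_init__(self) -> None:
        if self.n_diagnostic > self.n_loci:
            raise ValueError("n_diagnostic cannot exceed n_loci")
        if not (0 <= self.missing_rate < 1):
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.locus_names) < self.n_loci:
            extra = [f"L{i + 1}" for i in range(self.n_loci - len(self.locus_names))]
            self.locus_names = tuple(self.locus_names) + tuple(extra)
        self.locus_names = tuple(self.locus_names[: self.n_loci])
        self.diagnostic_names = tuple(
            n for n in self.diagnostic_names if n in self.locus_names
        )[: self.n_diagnostic]
        if len(self.diagnostic_names) < self.n_diagnostic:
            pool = [n for n in self.locus_names if n not in self.diagnostic_names]
            self.diagnostic_names += tuple(pool[: self.n_diagnostic - len(self.diagnostic_names)])


@dataclass
class SyntheticTruth:
    """Ground truth stored alongside generated data for recovery tests."""

    freqsA: dict[str, dict[int, float]]
    freqsB: dict[str, dict[int, float]]
    class_map: dict[str, dict[int, str]]
    diagnostic_loci: list[str]
    h_star: dict[str, float] = field(default_factory=dict)
    swarm_age: int | None = None

    def realized_delta(self, locus: str) -> float:
        fa, fb = self.freqsA[locus], self.freqsB[locus]
        alleles = set(fa) | set(fb)
        return 0.5 * sum(abs(fa.get(a, 0.0) - fb.get(a, 0.0)) for a in alleles)


# ---------------------------------------------------------------------------
# Frequencies and parental pools
# ---------------------------------------------------------------------------


def _hwe_genotypes(freqs: dict[int, float], n: int, rng: np.random.Generator) -> np.ndarray:
    """(n, 2) allele-code pairs drawn under Hardy–Weinberg equilibrium."""
    alleles = np.array(sorted(freqs))
    p = np.array([freqs[a] for a in alleles])
    p = p / p.sum()
    return alleles[rng.choice(len(alleles), size=(n, 2), p=p)]


def _diagnostic_freqs(
    k: int, delta: float, rng: np.random.Generator
) -> tuple[dict[int, float], dict[int, float]]:
    """Frequency vectors over k alleles (codes 1..k) split into two disjoint
    classes, with differential exactly ``delta``: each population puts mass
    m = (1+delta)/2 on its own class, sharing within-class shapes."""
    if k < 2:
        raise ValueError("diagnostic locus needs at least 2 alleles")
    k_a = max(1, k // 2)
    class_a = list(range(1, k_a + 1))
    class_b = list(range(k_a + 1, k + 1))
    # one dominant allele per class ("nearly fixed" diagnostic semantics)
    shape_a = np.sort(rng.dirichlet(np.ones(len(class_a)) * 0.5))[::-1]
    shape_b = np.sort(rng.dirichlet(np.ones(len(class_b)) * 0.5))[::-1]
    m = (1.0 + delta) / 2.0
    fa = {a: m * w for a, w in zip(class_a, shape_a)}
    fa.update({b: (1 - m) * w for b, w in zip(class_b, shape_b)})
    fb = {a: (1 - m) * w for a, w in zip(class_a, shape_a)}
    fb.update({b: m * w for b, w in zip(class_b, shape_b)})
    return fa, fb


def generate_parental_pools(
    design: SyntheticDesign, rng: np.random.Generator | None = None
) -> tuple[GenotypeTable, GenotypeTable, SyntheticTruth]:
    """Genotype pools for the two parental populations.

    Diagnostic loci carry a frequency differential of exactly
    ``design.delta_target`` between disjoint allele classes; non-diagnostic
    loci share a common Dirichlet frequency vector with mild per-population
    noise.  Genotypes are sampled under HWE.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    lo, hi = design.alleles_per_locus
    freqsA: dict[str, dict[int, float]] = {}
    freqsB: dict[str, dict[int, float]] = {}
    for locus in design.locus_names:
        k = int(rng.integers(lo, hi + 1))
        if locus in design.diagnostic_names:
            # diagnostic loci carry few, nearly fixed alleles per class
            k = int(np.clip(k, 2, 4))
            freqsA[locus], freqsB[locus] = _diagnostic_freqs(k, design.delta_target, rng)
        else:
            base = rng.dirichlet(np.ones(k))
            concentration = 100.0  # mild between-population noise
            pa = rng.dirichlet(base * concentration + 1e-3)
            pb = rng.dirichlet(base * concentration + 1e-3)
            freqsA[locus] = {i + 1: float(v) for i, v in enumerate(pa)}
            freqsB[locus] = {i + 1: float(v) for i, v in enumerate(pb)}
    nA = design.pop_sizes[design.pop_a]
    nB = design.pop_sizes[design.pop_b]
    allelesA = np.stack(
        [_hwe_genotypes(freqsA[l], nA, rng) for l in design.locus_names], axis=1
    )
    allelesB = np.stack(
        [_hwe_genotypes(freqsB[l], nB, rng) for l in design.locus_names], axis=1
    )
    samplesA = [f"{design.pop_a}{i + 1:02d}" for i in range(nA)]
    samplesB = [f"{design.pop_b}{i + 1:02d}" for i in range(nB)]
    class_map = {
        locus: {
            a: ("A" if freqsA[locus].get(a, 0.0) > freqsB[locus].get(a, 0.0) else "B")
            for a in set(freqsA[locus]) | set(freqsB[locus])
            if freqsA[locus].get(a, 0.0) != freqsB[locus].get(a, 0.0)
        }
        for locus in design.locus_names
    }
    truth = SyntheticTruth(freqsA, freqsB, class_map, list(design.diagnostic_names))
    loci = list(design.locus_names)
    return (
        GenotypeTable(samplesA, loci, allelesA),
        GenotypeTable(samplesB, loci, allelesB),
        truth,
    )


# ---------------------------------------------------------------------------
# Hybrid swarm with tracked ancestry
# ---------------------------------------------------------------------------


def _tracked_gametes(
    alleles: np.ndarray, origins: np.ndarray, n_off: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    n_ind, L, _ = alleles.shape
    parents = rng.integers(0, n_ind, size=n_off)
    which = rng.integers(0, 2, size=(n_off, L))
    cols = np.arange(L)[None, :]
    return (
        alleles[parents[:, None], cols, which],
        origins[parents[:, None], cols, which],
    )


def generate_hybrid_swarm(
    poolA: GenotypeTable,
    poolB: GenotypeTable,
    age: int,
    N: int,
    rng: np.random.Generator,
    n_samples: int | None = None,
    sample_prefix: str = "SHY",
) -> tuple[GenotypeTable, SyntheticTruth]:
    """Breed a hybrid swarm for ``age`` generations (generation 1 = F1) and
    sample individuals, tracking the true ancestry proportion h* of every
    copy (fraction of the genome descending from pool A)."""
    if age < 1:
        raise ValueError("age must be >= 1 (generation 1 is the F1)")
    if (poolA.alleles == MISSING).any() or (poolB.alleles == MISSING).any():
        raise ValueError("parental pools must be fully called for ancestry tracking")
    L = len(poolA.loci)
    gamA, _ = _tracked_gametes(poolA.alleles, np.zeros_like(poolA.alleles), N, rng)
    gamB, _ = _tracked_gametes(poolB.alleles, np.zeros_like(poolB.alleles), N, rng)
    alleles = np.stack([gamA, gamB], axis=2)
    origins = np.zeros_like(alleles)
    origins[:, :, 1] = 1  # copy 1 of the F1 comes from pool B
    for _ in range(age - 1):
        a1, o1 = _tracked_gametes(alleles, origins, N, rng)
        a2, o2 = _tracked_gametes(alleles, origins, N, rng)
        alleles = np.stack([a1, a2], axis=2)
        origins = np.stack([o1, o2], axis=2)
    if n_samples is None:
        n_samples = N
    if n_samples > N:
        raise ValueError("cannot sample more individuals than the census size")
    idx = rng.choice(N, size=n_samples, replace=False)
    h_star = 1.0 - origins[idx].mean(axis=(1, 2))  # origin 0 = pool A
    samples = [f"{sample_prefix}{i + 1:02d}" for i in range(n_samples)]
    truth = SyntheticTruth(
        freqsA={}, freqsB={}, class_map={}, diagnostic_loci=[],
        h_star={s: float(h) for s, h in zip(samples, h_star)}, swarm_age=age,
    )
    return GenotypeTable(samples, list(poolA.loci), alleles[idx]), truth


# ---------------------------------------------------------------------------
# Drifted outgroup populations
# ---------------------------------------------------------------------------


def drifted_frequencies(
    freqs: dict[int, float],
    target_fst: float,
    rng: np.random.Generator,
    bottleneck_2n: int = 40,
) -> dict[int, float]:
    """Drift a frequency vector so that the drifted population's expected
    pairwise FST against its undrifted source is ``target_fst``.

    Pure drift with inbreeding coefficient F inflates Var(p) by p(1−p)F,
    giving an expected pairwise Gst of roughly (F/4)/(1 − F/4) against the
    source; inverting, F = 4T/(1+T) (capped below 1 — drift from a shared
    source cannot push this Gst much beyond 1/3, which is why only
    between-species pairs reach higher values).  The drift is realized by
    iterating multinomial resampling in a bottleneck of ``bottleneck_2n``
    allele copies for g = ln(1−F)/ln(1−1/2N) generations.
    """
    if not (0 <= target_fst < 1):
        raise ValueError("target_fst must be in [0, 1)")
    if target_fst == 0:
        return dict(freqs)
    F = min(4.0 * target_fst / (1.0 + target_fst), 0.97)
    g = int(round(np.log(1 - F) / np.log(1 - 1.0 / bottleneck_2n)))
    alleles = sorted(freqs)
    p = np.array([freqs[a] for a in alleles])
    p = p / p.sum()
    for _ in range(max(g, 1)):
        counts = rng.multinomial(bottleneck_2n, p)
        p = counts / bottleneck_2n
    return {a: float(v) for a, v in zip(alleles, p) if v > 0}


def generate_outgroup(
    base_freqs: Mapping[str, Mapping[int, float]],
    loci: Sequence[str],
    name: str,
    n: int,
    target_fst: float,
    rng: np.random.Generator,
) -> GenotypeTable:
    """A population drifted away from ``base_freqs`` toward ``target_fst``."""
    cols = []
    for locus in loci:
        f = drifted_frequencies(dict(base_freqs[locus]), target_fst, rng)
        cols.append(_hwe_genotypes(f, n, rng))
    samples = [f"{name}{i + 1:02d}" for i in range(n)]
    return GenotypeTable(samples, list(loci), np.stack(cols, axis=1))


# ---------------------------------------------------------------------------
# Missingness
# ---------------------------------------------------------------------------


def inject_missingness(
    genotypes: GenotypeTable,
    rate: float,
    rng: np.random.Generator,
    per_locus_rates: Mapping[str, float] | None = None,
) -> tuple[GenotypeTable, pd.Series]:
    """Mask whole genotype cells missing-completely-at-random.

    ``per_locus_rates`` overrides the global rate per locus.  Returns the
    masked table and the realized per-locus missing rates.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    alleles = genotypes.alleles.copy()
    for j, locus in enumerate(genotypes.loci):
        r = rate if per_locus_rates is None else per_locus_rates.get(locus, rate)
        mask = rng.random(len(genotypes.samples)) < r
        alleles[mask, j, :] = MISSING
    masked = GenotypeTable(list(genotypes.samples), list(genotypes.loci), alleles)
    return masked, masked.missing_report()


def default_missing_profile(loci: Sequence[str]) -> dict[str, float]:
    """Per-locus missing rates emulating the empirical profile: one
    unusually high locus (VIM_new-like, 25.3%), the rest spread over
    1.1%–13.8%."""
    loci = list(loci)
    high = "VIM_new" if "VIM_new" in loci else loci[-1]
    others = [l for l in loci if l != high]
    rates = np.linspace(0.011, 0.138, len(others)) if others else []
    profile = {l: float(r) for l, r in zip(others, rates)}
    profile[high] = 0.253
    return profile


# ---------------------------------------------------------------------------
# Geography
# ---------------------------------------------------------------------------


def _genetic_axis(genotypes: GenotypeTable, samples: Sequence[str]) -> np.ndarray:
    """Standardized first principal component of one-hot allele counts for
    the given samples (a latent within-population genetic gradient)."""
    sub = genotypes.subset_samples(samples)
    blocks = []
    for j in range(len(sub.loci)):
        cells = sub.alleles[:, j, :]
        alleles = np.unique(cells[cells != MISSING])
        for a in alleles:
            blocks.append((cells == a).sum(axis=1).astype(float))
    X = np.column_stack(blocks) if blocks else np.zeros((len(samples), 1))
    X = X - X.mean(axis=0)
    if np.allclose(X, 0):
        return np.zeros(len(samples))
    _, _, vt = np.linalg.svd(X, full_matrices=False)
    axis = X @ vt[0]
    sd = axis.std()
    return axis / sd if sd > 0 else axis


def generate_geography(
    meta: SampleMetadata,
    genotypes: GenotypeTable,
    ibd_strength: float,
    rng: np.random.Generator,
    centers: Mapping[str, tuple[float, float]] | None = None,
    spread_deg: float = 0.25,
) -> SampleMetadata:
    """Assign coordinates: populations sit at fixed arbitrary centres
    (between-population geography carries no ancestry signal), and within
    each population the latitude tracks a latent genetic gradient with
    weight ibd_strength/(1+ibd_strength), producing isolation by distance
    within but not between populations.  ibd_strength = 0 gives pure noise.
    """
    if ibd_strength < 0:
        raise ValueError("ibd_strength must be >= 0")
    if centers is None:
        centers = DEFAULT_CENTERS
    table = meta.table.copy()
    w = ibd_strength / (1.0 + ibd_strength)
    for pop in meta.populations:
        samples = [s for s in meta.samples_in(pop) if s in genotypes.samples]
        if not samples:
            continue
        clat, clon = centers.get(pop, (20.0, 108.0))
        axis = _genetic_axis(genotypes, samples)
        n = len(samples)
        noise_lat = rng.normal(size=n)
        noise_lon = rng.normal(size=n)
        lat = clat + spread_deg * (w * axis + (1 - w) * noise_lat)
        lon = clon + spread_deg * noise_lon
        table.loc[samples, "lat"] = np.clip(lat, clat - spread_deg * 4, clat + spread_deg * 4)
        table.loc[samples, "lon"] = np.clip(lon, clon - spread_deg * 4, clon + spread_deg * 4)
    return SampleMetadata(table.reset_index(drop=True), meta.populations)


# ---------------------------------------------------------------------------
# Sequences (nuclear haplotypes + mitochondrial CytB)
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _mutate(seq: np.ndarray, positions: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    for p in positions:
        choices = [b for b in "ACGT" if b != out[p]]
        out[p] = choices[rng.integers(0, 3)]
    return out


def allele_sequences(
    n_alleles: int, length: int, rng: np.random.Generator
) -> dict[int, str]:
    """Distinct aligned haplotype sequences for allele codes 1..n:
    allele 1 is the base sequence; allele i carries a private substitution
    at its own dedicated site (plus shared polymorphic background)."""
    if length < n_alleles + 1:
        raise ValueError("alignment too short for the requested allele count")
    base = _random_sequence(length, rng)
    sites = rng.choice(length, size=n_alleles - 1, replace=False) if n_alleles > 1 else []
    out = {1: "".join(base)}
    for i, site in enumerate(sites, start=2):
        out[i] = "".join(_mutate(base, np.array([site]), rng))
    return out


def cytb_haplotypes(
    rng: np.random.Generator,
    clade_divergence: float = 0.09,
    subclade_divergence: float = 0.03,
    within_divergence: float = 0.005,
    length: int = CYTB_LENGTH,
) -> dict[str, dict[str, str]]:
    """Mitochondrial haplotype sets per population: one deeply divergent
    parental-A clade and a parental-B clade containing three subclades
    (the B parent, the hybrid-donor subclade included)."""
    base = _random_sequence(length, rng)

    def derive(seq: np.ndarray, div: float) -> np.ndarray:
        k = max(1, int(round(div * length)))
        return _mutate(seq, rng.choice(length, size=k, replace=False), rng)

    clade_a = derive(base, clade_divergence)
    sub_en = base
    sub_wn = derive(base, subclade_divergence)
    sub_es = derive(base, subclade_divergence)
    out: dict[str, dict[str, str]] = {
        "SBE": {f"SBE{i + 1:02d}": "".join(derive(clade_a, within_divergence))
                for i in range(3)},
        "SQUen": {f"SQUen{i + 1:02d}": "".join(derive(sub_en, within_divergence))
                  for i in range(3)},
        "SQUwn": {f"SQUwn{i + 1:02d}": "".join(derive(sub_wn, within_divergence))
                  for i in range(2)},
        "SQUes": {f"SQUes{i + 1:02d}": "".join(derive(sub_es, within_divergence))
                  for i in range(2)},
    }
    return out


# ---------------------------------------------------------------------------
# Full study bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    """Paths and in-memory truth of one generated study."""

    root: Path
    loci_dir: Path
    metadata_csv: Path
    qmatrix_file: Path
    cytb_fasta: Path
    truth: SyntheticTruth
    genotypes: GenotypeTable
    meta: SampleMetadata
    qmatrix: QMatrix
    substructure_samples: list[str]


def _emulated_qmatrix(
    meta: SampleMetadata,
    design: SyntheticDesign,
    low_q_samples: Sequence[str],
    rng: np.random.Generator,
    noise_sd: float = 0.4,
) -> QMatrix:
    """Ancestry-coefficient matrix emulating an external clustering run:
    K = number of populations, representatives near 1 on their own cluster
    (logit-normal noise), early-admixture individuals below the 0.85 bar."""
    pops = list(meta.populations)
    K = len(pops)
    low = set(low_q_samples)
    rows = []
    for s in meta.samples:
        pop = meta.population_of(s)
        k = pops.index(pop)
        if s in low:
            qmax = rng.uniform(0.55, 0.84)
        else:
            logit = rng.normal(3.5, noise_sd)  # ~0.97 own-cluster affiliation
            qmax = 1.0 / (1.0 + np.exp(-logit))
            qmax = max(qmax, 0.86)
        rest = rng.dirichlet(np.ones(K - 1)) * (1 - qmax)
        row = np.insert(rest, k, qmax)
        rows.append(row)
    return QMatrix(list(meta.samples), np.array(rows))


def generate_study_bundle(
    design: SyntheticDesign, outdir: str | Path
) -> StudyBundle:
    """Generate and write a complete synthetic study to ``outdir``:
    per-locus phased FASTA alignments, a metadata CSV (population,
    locality, coordinates, mtDNA haplotype, substructure flag), an
    ancestry-coefficient matrix, and a CytB haplotype FASTA.
    """
    rng = np.random.default_rng(design.seed)
    outdir = Path(outdir)
    loci_dir = outdir / "loci"
    loci_dir.mkdir(parents=True, exist_ok=True)

    poolA, poolB, truth = generate_parental_pools(design, rng)
    truth.swarm_age = design.swarm_age
    swarm, swarm_truth = generate_hybrid_swarm(
        poolA, poolB, design.swarm_age, design.swarm_N, rng,
        n_samples=design.pop_sizes[design.pop_hybrid],
        sample_prefix=design.pop_hybrid,
    )
    truth.h_star.update(swarm_truth.h_star)
    truth.h_star.update({s: 1.0 for s in poolA.samples})
    truth.h_star.update({s: 0.0 for s in poolB.samples})

    loci = list(design.locus_names)
    outgroups = []
    for pop, fst in (("SQUwn", design.fst_outgroup), ("SQUes", design.fst_island)):
        if pop in design.pop_sizes:
            outgroups.append(
                generate_outgroup(truth.freqsB, loci, pop,
                                  design.pop_sizes[pop], fst, rng)
            )

    # early-admixture (low-Q) and substructure extras
    extras: list[GenotypeTable] = []
    low_q_samples: list[str] = []
    substructure_samples: list[str] = []
    pool_of = {design.pop_a: poolA, design.pop_b: poolB}
    for pop, n in design.n_low_q.items():
        if n <= 0:
            continue
        own = pool_of.get(pop, poolB)
        other = poolA if own is not poolB else poolB
        bc, _ = generate_hybrid_swarm(own, other, 1, max(n, 2), rng,
                                      n_samples=n, sample_prefix=f"{pop}x")
        extras.append(bc)
        low_q_samples += bc.samples
    for pop, n in design.n_substructure.items():
        if n <= 0:
            continue
        sub = generate_outgroup(
            truth.freqsB if pop != design.pop_a else truth.freqsA,
            loci, f"{pop}s", n, 0.2, rng,
        )
        extras.append(sub)
        substructure_samples += sub.samples

    tables = [poolA, poolB, swarm] + outgroups + extras
    samples = [s for t in tables for s in t.samples]
    alleles = np.concatenate([t.alleles for t in tables], axis=0)
    genotypes = GenotypeTable(samples, loci, alleles)

    pop_label = {}
    for t, pop in zip(
        [poolA, poolB, swarm] + outgroups,
        [design.pop_a, design.pop_b, design.pop_hybrid] + ["SQUwn", "SQUes"],
    ):
        for s in t.samples:
            pop_label[s] = pop
    for s in low_q_samples + substructure_samples:
        for pop in design.pop_sizes:
            if s.startswith(pop):
                pop_label[s] = pop

    mthaps = cytb_haplotypes(rng)
    # the hybrid swarm carries parental-B (SQUen) mitochondrial haplotypes
    hap_source = {
        design.pop_a: "SBE", design.pop_b: "SQUen",
        design.pop_hybrid: "SQUen", "SQUwn": "SQUwn", "SQUes": "SQUes",
    }
    meta_rows = []
    for s in samples:
        pop = pop_label[s]
        hap_pool = list(mthaps[hap_source.get(pop, "SQUen")])
        meta_rows.append(
            {
                "sample_id": s,
                "population": pop,
                "locality": f"{pop}_site{rng.integers(1, 4)}",
                "lat": np.nan,
                "lon": np.nan,
                "mthap": hap_pool[rng.integers(0, len(hap_pool))],
                "substructure": s in substructure_samples,
            }
        )
    meta = SampleMetadata(pd.DataFrame(meta_rows), tuple(design.pop_sizes))
    meta = generate_geography(meta, genotypes, design.ibd_strength, rng)

    profile = design.per_locus_missing or default_missing_profile(loci)
    genotypes, realized = inject_missingness(
        genotypes, design.missing_rate, rng, per_locus_rates=profile
    )

    qmat = _emulated_qmatrix(meta, design, low_q_samples, rng)

    # write everything
    catalogs = {
        locus: allele_sequences(
            int(max(
                [a for f in (truth.freqsA[locus], truth.freqsB[locus]) for a in f],
                default=1,
            )),
            DEFAULT_LOCI.get(locus, 500),
            rng,
        )
        for locus in loci
    }
    for j, locus in enumerate(loci):
        lines = []
        for i, s in enumerate(samples):
            for phase in (1, 2):
                code = int(genotypes.alleles[i, j, phase - 1])
                if code == MISSING:
                    continue
                lines.append(f">{s}|{locus}|{phase}")
                lines.append(catalogs[locus][code])
        (loci_dir / f"{locus}.fasta").write_text("\n".join(lines) + "\n")

    cytb_fasta = outdir / "cytb.fasta"
    cytb_lines = []
    for pop_haps in mthaps.values():
        for name, seq in pop_haps.items():
            cytb_lines += [f">{name}", seq]
    cytb_fasta.write_text("\n".join(cytb_lines) + "\n")

    metadata_csv = outdir / "metadata.csv"
    meta.write_csv(metadata_csv)
    qmatrix_file = outdir / "qmatrix.txt"
    write_qmatrix(qmat, qmatrix_file)

    truth_file = outdir / "truth.json"
    truth_file.write_text(json.dumps(
        {
            "diagnostic_loci": truth.diagnostic_loci,
            "swarm_age": truth.swarm_age,
            "h_star": truth.h_star,
            "realized_delta": {l: truth.realized_delta(l) for l in loci},
        },
        indent=1,
    ))

    return StudyBundle(
        outdir, loci_dir, metadata_csv, qmatrix_file, cytb_fasta,
        truth, genotypes, meta, qmat, substructure_samples,
    )
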