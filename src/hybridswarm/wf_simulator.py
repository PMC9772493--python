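"""Forward-time hybridization and genetic-drift simulation.

The model is the canonical neutral Wright–Fisher process for a closed
diploid population of constant size N with non-overlapping generations,
monoecious random mating with selfing allowed, free recombination between
loci, and no mutation, selection or migration.  The simulated scenario is:

1. generation 1 is an F1 cross — each of the N offspring takes one gamete
   from a random individual of parental pool A and one from a random
   individual of pool B;
2. generations 2 … n_generations+1 are closed random mating within the
   hybrid population (two parents drawn independently and uniformly with
   replacement; each transmits one uniformly chosen allele per locus).

Under this scheme every allele copy in the next generation is an
independent uniform draw from the 2N parental copies, so a biallelic
locus's count follows the classical Binomial(2N, p) resampling chain, with
mean absorption time −4N (p ln p + q ln q) generations in the diffusion
limit.

"Fixation" of a locus is assessed against the parental *class* partition of
alleles (the parental pools are multi-allelic): a locus is fixed once all
2N copies descend from a single parental class, even if several allele
codes of that class still segregate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotype_io import MISSING, GenotypeTable
from . import hybrid_ancestry

DEFAULT_CHECKPOINTS = (1, 2, 5, 10, 20, 50, 100, 200, 500)


@dataclass
class SimulationConfig:
    """Parameters of the hybridization + drift simulation."""

    N: int = 100
    n_generations: int = 999  # breeding generations after the F1
    replicates: int = 4
    checkpoints: tuple[int, ...] = DEFAULT_CHECKPOINTS
    seed: int | None = None
    #: stop a replicate once all loci are fixed and every checkpoint has
    #: been recorded (the class frequencies cannot change afterwards)
    stop_when_fixed: bool = False
    rng_algorithm: str = "numpy PCG64 via SeedSequence spawn"

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.n_generations < 0:
            raise ValueError("n_generations must be >= 0")
        horizon = self.n_generations + 1
        bad = [c for c in self.checkpoints if not (1 <= c <= horizon)]
        if bad:
            raise ValueError(f"checkpoints {bad} outside [1, {horizon}]")
        self.checkpoints = tuple(sorted(set(int(c) for c in self.checkpoints)))

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "checkpoints" in d:
            d["checkpoints"] = tuple(d["checkpoints"])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "N": self.N,
            "n_generations": self.n_generations,
            "replicates": self.replicates,
            "checkpoints": list(self.checkpoints),
            "seed": self.seed,
            "stop_when_fixed": self.stop_when_fixed,
            "rng_algorithm": self.rng_algorithm,
        }


@dataclass
class SimulationTrajectory:
    """One replicate: checkpoint snapshots, fixation record, frequency series."""

    replicate: int
    loci: list[str]
    #: generation -> (N, L, 2) allele array
    snapshots: dict[int, np.ndarray]
    #: per locus: first generation with a single surviving parental class,
    #: or None if still segregating at the horizon (right-censored)
    fixation_generation: dict[str, int | None]
    #: (n_recorded, L) class-A allele frequency; row g-1 is generation g
    allele_freq_series: np.ndarray
    generations_recorded: int

    def snapshot_table(self, generation: int) -> GenotypeTable:
        arr = self.snapshots[generation]
        samples = [f"rep{self.replicate}_g{generation}_ind{i + 1}"
                   for i in range(arr.shape[0])]
        return GenotypeTable(samples, list(self.loci), arr.copy())

    @property
    def all_fixed_generation(self) -> int | None:
        gens = list(self.fixation_generation.values())
        if any(g is None for g in gens):
            return None
        return max(gens)  # type: ignore[type-var]


# ---------------------------------------------------------------------------
# Core sampling steps (array in, array out)
# ---------------------------------------------------------------------------


def _gametes(pool: np.ndarray, n_off: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``n_off`` gametes (one allele per locus, loci independent) from
    uniformly chosen parents in ``pool`` ((n_ind, L, 2) allele array).
    Missing parental alleles are resolved by redrawing the parent for that
    locus."""
    n_ind, L, _ = pool.shape
    parents = rng.integers(0, n_ind, size=n_off)
    which = rng.integers(0, 2, size=(n_off, L))
    out = pool[parents[:, None], np.arange(L)[None, :], which]
    # redraw (offspring, locus) cells that hit a missing parental copy
    for _ in range(10_000):
        miss = out == MISSING
        if not miss.any():
            return out
        oi, li = np.nonzero(miss)
        repar = rng.integers(0, n_ind, size=oi.size)
        rewhich = rng.integers(0, 2, size=oi.size)
        out[oi, li] = pool[repar, li, rewhich]
    bad = int(np.nonzero((out == MISSING).any(axis=0))[0][0])
    raise ValueError(f"locus index {bad} has no callable alleles in the pool")


def make_f1(
    poolA: GenotypeTable | np.ndarray,
    poolB: GenotypeTable | np.ndarray,
    N: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """First hybrid generation: one gamete from each parental pool per
    offspring.  Returns an (N, L, 2) allele array (copy 0 from pool A)."""
    a = poolA.alleles if isinstance(poolA, GenotypeTable) else np.asarray(poolA)
    b = poolB.alleles if isinstance(poolB, GenotypeTable) else np.asarray(poolB)
    if a.size == 0 or b.size == 0:
        raise ValueError("parental pools must be nonempty")
    if N < 1:
        raise ValueError("N must be >= 1")
    if a.shape[1] != b.shape[1]:
        raise ValueError("parental pools must cover the same loci")
    return np.stack([_gametes(a, N, rng), _gametes(b, N, rng)], axis=2)


def breed_generation(
    pop: GenotypeTable | np.ndarray, N: int, rng: np.random.Generator
) -> np.ndarray:
    """One Wright–Fisher generation: each of N offspring draws two parents
    independently and uniformly with replacement (selfing possible) and one
    gamete from each."""
    arr = pop.alleles if isinstance(pop, GenotypeTable) else np.asarray(pop)
    if arr.size == 0:
        raise ValueError("population must be nonempty")
    return np.stack([_gametes(arr, N, rng), _gametes(arr, N, rng)], axis=2)


# ---------------------------------------------------------------------------
# Full protocol
# ---------------------------------------------------------------------------


def derive_class_map(
    poolA: GenotypeTable, poolB: GenotypeTable
) -> dict[str, dict[int, str]]:
    """Parental class per allele from the pools themselves: the class is the
    pool where the allele's relative frequency is higher (ties unassigned)."""
    class_map: dict[str, dict[int, str]] = {}
    for j, locus in enumerate(poolA.loci):
        m: dict[int, str] = {}
        fa = _pool_freqs(poolA.alleles[:, j, :])
        fb = _pool_freqs(poolB.alleles[:, poolB.locus_index(locus), :])
        for a in set(fa) | set(fb):
            if fa.get(a, 0.0) > fb.get(a, 0.0):
                m[a] = "A"
            elif fb.get(a, 0.0) > fa.get(a, 0.0):
                m[a] = "B"
        class_map[locus] = m
    return class_map


def _pool_freqs(cells: np.ndarray) -> dict[int, float]:
    copies = cells[cells != MISSING]
    if copies.size == 0:
        return {}
    alleles, counts = np.unique(copies, return_counts=True)
    return {int(a): float(c) / copies.size for a, c in zip(alleles, counts)}


def _class_a_matrix(loci: Sequence[str], class_map: Mapping[str, Mapping[int, str]],
                    max_code: int) -> np.ndarray:
    """is_a[j, code] = 1 if allele ``code`` at locus j belongs to class A."""
    is_a = np.zeros((len(loci), max_code + 1), dtype=bool)
    for j, locus in enumerate(loci):
        for code, cls in class_map.get(locus, {}).items():
            if cls == "A" and 0 <= code <= max_code:
                is_a[j, code] = True
    return is_a


def run_simulation(
    cfg: SimulationConfig,
    poolA: GenotypeTable,
    poolB: GenotypeTable,
    class_map: Mapping[str, Mapping[int, str]] | None = None,
) -> list[SimulationTrajectory]:
    """Run the full F1 + closed-breeding protocol for every replicate.

    Each replicate uses an independent deterministic substream of the
    master seed, so a fixed seed reproduces trajectories bit-for-bit.
    """
    if poolA.loci != poolB.loci:
        raise ValueError("parental pools must list the same loci in the same order")
    loci = list(poolA.loci)
    if class_map is None:
        class_map = derive_class_map(poolA, poolB)
    max_code = int(max(poolA.alleles.max(), poolB.alleles.max(), 1))
    is_a = _class_a_matrix(loci, class_map, max_code)
    streams = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    horizon = cfg.n_generations + 1
    last_checkpoint = max(cfg.checkpoints) if cfg.checkpoints else 1
    trajectories: list[SimulationTrajectory] = []
    for rep, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        pop = make_f1(poolA, poolB, cfg.N, rng)  # generation 1
        snapshots: dict[int, np.ndarray] = {}
        fix_gen: dict[str, int | None] = {l: None for l in loci}
        freq_rows = np.empty((horizon, len(loci)))
        gen = 1
        while True:
            freq_a = is_a[np.arange(len(loci))[None, :, None], pop].mean(axis=(0, 2))
            freq_rows[gen - 1] = freq_a
            for j, locus in enumerate(loci):
                if fix_gen[locus] is None and (freq_a[j] == 0.0 or freq_a[j] == 1.0):
                    fix_gen[locus] = gen
            if gen in cfg.checkpoints:
                snapshots[gen] = pop.copy()
            done = gen >= horizon
            if cfg.stop_when_fixed and gen >= last_checkpoint and \
                    all(g is not None for g in fix_gen.values()):
                done = True
            if done:
                break
            pop = breed_generation(pop, cfg.N, rng)
            gen += 1
        trajectories.append(
            SimulationTrajectory(rep, loci, snapshots, fix_gen,
                                 freq_rows[:gen].copy(), gen)
        )
    return trajectories


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------


def fixation_summary(trajs: Sequence[SimulationTrajectory]) -> pd.DataFrame:
    """Per-replicate first all-loci-fixed generation plus per-locus fixation
    generations; unfixed loci at the horizon are right-censored (NaN with
    the censored flag set)."""
    if not trajs:
        raise ValueError("need at least one trajectory")
    rows = []
    for t in trajs:
        row: dict[str, object] = {"replicate": t.replicate}
        censored = False
        for locus, g in t.fixation_generation.items():
            row[f"fix_{locus}"] = np.nan if g is None else g
            censored |= g is None
        allg = t.all_fixed_generation
        row["all_fixed_generation"] = np.nan if allg is None else allg
        row["censored"] = censored
        row["horizon"] = t.generations_recorded
        rows.append(row)
    return pd.DataFrame(rows)


def per_locus_fixation_quantiles(
    trajs: Sequence[SimulationTrajectory], q: Sequence[float] = (0.25, 0.5, 0.75)
) -> pd.DataFrame:
    loci = trajs[0].loci
    rows = []
    for locus in loci:
        gens = [t.fixation_generation[locus] for t in trajs]
        observed = [g for g in gens if g is not None]
        row = {"locus": locus, "n_censored": sum(g is None for g in gens)}
        for qq in q:
            row[f"q{int(qq * 100)}"] = (
                float(np.quantile(observed, qq)) if observed else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def simulated_ancestry_composition(
    trajs: Sequence[SimulationTrajectory],
    diagnostic_loci: Sequence[str],
    class_map: Mapping[str, Mapping[int, str]],
    freqsA: Mapping[str, Mapping[int, float]],
    freqsB: Mapping[str, Mapping[int, float]],
) -> pd.DataFrame:
    """Ancestry make-up of every checkpoint snapshot: per-locus proportions
    of both-A / both-B / mixed genotypes and the mean ML hybrid index of the
    simulated individuals (the simulated analogue of the per-individual
    ancestry plot)."""
    rows = []
    for t in trajs:
        for gen in sorted(t.snapshots):
            table = t.snapshot_table(gen)
            cats = hybrid_ancestry.ancestry_categories(table, diagnostic_loci, class_map)
            results = [
                hybrid_ancestry.hybrid_index_ml(
                    table.alleles[i], freqsA, freqsB, diagnostic_loci,
                    table.loci, table.samples[i], class_map,
                )
                for i in range(len(table.samples))
            ]
            h = np.array([r.h for r in results])
            for locus in diagnostic_loci:
                col = cats[locus]
                n_ok = (col != "missing").sum()
                rows.append(
                    {
                        "replicate": t.replicate,
                        "generation": gen,
                        "locus": locus,
                        "prop_both_A": (col == "both-A").sum() / max(n_ok, 1),
                        "prop_both_B": (col == "both-B").sum() / max(n_ok, 1),
                        "prop_mixed": (col == "mixed").sum() / max(n_ok, 1),
                        "mean_h": float(h.mean()),
                    }
                )
    return pd.DataFrame(rows)


def export_snapshots(
    trajs: Sequence[SimulationTrajectory], outdir: str | Path
) -> list[Path]:
    """Write every checkpoint snapshot as a two-digit flat file."""
    from .genotype_io import write_structure_file

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for t in trajs:
        for gen in sorted(t.snapshots):
            path = outdir / f"rep{t.replicate}_gen{gen}.str"
            write_structure_file(t.snapshot_table(gen), path)
            written.append(path)
    return written


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))


def save_config(cfg: SimulationConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
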