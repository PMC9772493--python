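"""End-to-end analysis pipeline.

Runs the full study workflow from a YAML config: read per-locus FASTA
alignments, collapse haplotypes into coded genotypes, apply the
representative (Q) filter, compute diversity / FST / p-distance /
isolation-by-distance statistics, select diagnostic loci and estimate
per-individual hybrid indices, evaluate the isolated-offshoot vs
hybrid-swarm hypotheses, run the forward drift simulation, and emit
CSV/TSV/Markdown report tables plus a reproducibility manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import hybrid_ancestry, popgen_stats, synthetic_data, wf_simulator
from .genotype_io import (
    GenotypeTable,
    SampleMetadata,
    filter_representatives,
    genotypes_from_alignments,
    read_locus_fasta,
    read_qmatrix,
    write_structure_file,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips through YAML."""

    loci_dir: str = ""
    metadata_csv: str = ""
    qmatrix_file: str = ""
    output_dir: str = "results"
    populations: list[str] = field(default_factory=list)
    pop_a: str = "SBE"
    pop_b: str = "SQUen"
    pop_hybrid: str = "SHY"
    representative_threshold: float = 0.85
    exclude_samples: list[str] = field(default_factory=list)
    #: loci excluded from FST; empty means "apply the missing-rate rule"
    exclude_loci: list[str] = field(default_factory=list)
    max_locus_missing: float = 0.20
    rare_allele_min_count: int = 20
    diagnostic_delta_threshold: float = 0.8
    n_boot: int = 1000
    mantel_permutations: int = 9999
    simulation: wf_simulator.SimulationConfig = field(
        default_factory=wf_simulator.SimulationConfig
    )
    seed: int | None = None
    skip_simulation: bool = False
    skip_ibd: bool = False

    def __post_init__(self) -> None:
        if not (0 < self.representative_threshold < 1):
            raise ValueError("representative_threshold must be in (0, 1)")
        if not (0 < self.diagnostic_delta_threshold <= 1):
            raise ValueError("diagnostic_delta_threshold must be in (0, 1]")
        if self.rare_allele_min_count < 1:
            raise ValueError("rare_allele_min_count must be >= 1")
        if not (0 <= self.max_locus_missing <= 1):
            raise ValueError("max_locus_missing must be in [0, 1]")
        if isinstance(self.simulation, Mapping):
            self.simulation = wf_simulator.SimulationConfig.from_dict(self.simulation)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["simulation"] = self.simulation.to_dict()
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineResult:
    """Handles to the pipeline's in-memory results and output paths."""

    config: PipelineConfig
    output_dir: Path
    genotypes: GenotypeTable
    representatives: list[str]
    meta: SampleMetadata
    fst: popgen_stats.FstMatrix | None = None
    diversity: dict[str, pd.DataFrame] = field(default_factory=dict)
    diagnostic_loci: list[str] = field(default_factory=list)
    hybrid_indices: pd.DataFrame | None = None
    decision: hybrid_ancestry.AdmixtureDecision | None = None
    fixation: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order; any stage failure aborts with the
    failing stage named, leaving earlier outputs in place."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest(),
        "stages": {},
    }
    rng_seed = config.seed
    stage = "validate-inputs"
    try:
        loci_dir = Path(config.loci_dir)
        if not loci_dir.is_dir():
            raise FileNotFoundError(f"loci directory {loci_dir} not found")
        if not Path(config.metadata_csv).is_file():
            raise FileNotFoundError(f"metadata CSV {config.metadata_csv} not found")
        if not Path(config.qmatrix_file).is_file():
            raise FileNotFoundError(f"Q matrix {config.qmatrix_file} not found")

        stage = "io"
        fasta_files = sorted(loci_dir.glob("*.fasta")) + sorted(loci_dir.glob("*.fa"))
        alignments = [read_locus_fasta(p, p.stem) for p in fasta_files]
        if not alignments:
            raise FileNotFoundError(f"no FASTA alignments in {loci_dir}")
        meta = SampleMetadata.read_csv(
            config.metadata_csv, populations=config.populations
        )
        genotypes, catalogs = genotypes_from_alignments(
            alignments, samples=meta.samples
        )
        qmat = read_qmatrix(config.qmatrix_file, samples=meta.samples)
        manifest["stages"]["io"] = {
            "n_loci": len(genotypes.loci),
            "n_samples": len(genotypes.samples),
            "missing_rate": genotypes.missing_rate(),
        }

        stage = "filters"
        exclude = set(config.exclude_samples)
        if "substructure" in meta.table.columns:
            exclude |= set(
                meta.table.loc[meta.table["substructure"].fillna(False).astype(bool),
                               "sample_id"]
            )
        representatives = filter_representatives(
            qmat, config.representative_threshold, exclude
        )
        rep_table = genotypes.subset_samples(
            [s for s in genotypes.samples if s in set(representatives)]
        )
        rep_counts = {
            pop: sum(1 for s in representatives if meta.population_of(s) == pop)
            for pop in meta.populations
        }
        logger.info("representatives per population: %s", rep_counts)
        missing = rep_table.missing_report()
        if config.exclude_loci:
            fst_excluded = list(config.exclude_loci)
        else:
            fst_excluded = list(missing[missing > config.max_locus_missing].index)
        manifest["stages"]["filters"] = {
            "n_representatives": len(representatives),
            "representatives_per_population": rep_counts,
            "excluded_samples": sorted(exclude),
            "fst_excluded_loci": fst_excluded,
        }

        stage = "diversity"
        diversity_frames: dict[str, pd.DataFrame] = {}
        for pop in meta.populations:
            recs = popgen_stats.diversity(rep_table, meta, pop, seed=rng_seed)
            df = popgen_stats.diversity_table(recs)
            df["missing_rate"] = [missing[l] for l in df["locus"]]
            diversity_frames[pop] = df
        table3 = _table3(diversity_frames, missing)
        table3.to_csv(out / "diversity_table.csv", index=False)

        stage = "fst"
        fst = popgen_stats.nei_pairwise_fst(
            rep_table, meta, list(meta.populations),
            exclude_loci=fst_excluded, n_boot=config.n_boot, seed=rng_seed,
        )
        fst.to_frame().to_csv(out / "fst_table.csv")

        stage = "p-distance"
        concatenated = _concatenated_sequences(rep_table, catalogs)
        pdist = popgen_stats.p_distance(concatenated)
        pdist.to_phylip(out / "pdistance.phy")
        pdist.to_nexus(out / "pdistance.nex")

        stage = "ibd"
        ibd_within: dict[str, tuple[float, float]] = {}
        ibd_between = None
        if not config.skip_ibd:
            for pop in (config.pop_hybrid, config.pop_a, config.pop_b):
                pop_samples = [
                    s for s in meta.samples_in(pop) if s in pdist.labels
                ]
                geo = popgen_stats.geographic_distances(meta, pop_samples)
                if len(geo.labels) >= 4:
                    ibd_within[pop] = popgen_stats.mantel_ibd(
                        geo, pdist.submatrix(geo.labels),
                        n_perm=config.mantel_permutations, seed=rng_seed,
                    )
            all_geo = popgen_stats.geographic_distances(
                meta, [s for s in pdist.labels]
            )
            if len(all_geo.labels) >= 4:
                ibd_between = popgen_stats.mantel_ibd(
                    all_geo, pdist.submatrix(all_geo.labels),
                    n_perm=config.mantel_permutations, seed=rng_seed,
                )
            pd.DataFrame(
                [
                    {"scope": pop, "mantel_r": r, "p_value": p}
                    for pop, (r, p) in ibd_within.items()
                ]
                + (
                    [{"scope": "all", "mantel_r": ibd_between[0],
                      "p_value": ibd_between[1]}]
                    if ibd_between is not None else []
                )
            ).to_csv(out / "ibd_mantel.csv", index=False)

        stage = "diagnostics"
        analysis_pops = (config.pop_a, config.pop_b, config.pop_hybrid)
        analysis_samples = [
            s for s in representatives
            if meta.population_of(s) in analysis_pops and s in rep_table.samples
        ]
        filtered, dropped = hybrid_ancestry.rare_allele_filter(
            rep_table, analysis_samples, config.rare_allele_min_count
        )
        freqs = popgen_stats.allele_frequencies(filtered, meta, list(analysis_pops))
        usable_loci = [l for l in filtered.loci if l not in set(dropped)]
        diffs = hybrid_ancestry.allele_frequency_differential(
            freqs, config.pop_a, config.pop_b, usable_loci,
            threshold=config.diagnostic_delta_threshold,
        )
        pd.DataFrame(
            {"locus": [d.locus for d in diffs], "delta": [d.delta for d in diffs],
             "diagnostic": [d.diagnostic for d in diffs]}
        ).to_csv(out / "differentials.csv", index=False)
        diagnostic_loci = hybrid_ancestry.select_diagnostic_loci(
            diffs, config.diagnostic_delta_threshold
        )
        manifest["stages"]["diagnostics"] = {
            "rare_dropped_loci": dropped,
            "diagnostic_loci": diagnostic_loci,
            "n_analysis_samples": len(analysis_samples),
        }

        stage = "hybrid-index"
        hybrid_frame = None
        decision = None
        if diagnostic_loci:
            hy_samples = [
                s for s in analysis_samples
                if meta.population_of(s) == config.pop_hybrid
            ]
            results = hybrid_ancestry.hybrid_index_table(
                filtered, freqs, config.pop_a, config.pop_b,
                diagnostic_loci, hy_samples,
            )
            hybrid_frame = hybrid_ancestry.hybrid_index_frame(results)
            hybrid_frame.to_csv(out / "hybrid_index.csv", index=False)
            class_map = hybrid_ancestry.assign_parental_classes(
                freqs, config.pop_a, config.pop_b, diagnostic_loci
            )
            cats = hybrid_ancestry.ancestry_categories(
                filtered.subset_samples(hy_samples), diagnostic_loci, class_map
            )
            cats.to_csv(out / "ancestry_categories.tsv", sep="\t")

            stage = "hypothesis-test"
            decision = hybrid_ancestry.admixture_hypothesis_test(
                pdist, fst, meta, config.pop_hybrid, config.pop_a, config.pop_b,
                ibd_within=ibd_within or None, ibd_between=ibd_between,
            )
            (out / "hypothesis_report.txt").write_text(decision.report() + "\n")

        stage = "simulation"
        fixation = None
        if not config.skip_simulation and diagnostic_loci:
            sim_cfg = config.simulation
            if sim_cfg.seed is None and config.seed is not None:
                sim_cfg = wf_simulator.SimulationConfig.from_dict(
                    {**sim_cfg.to_dict(), "seed": config.seed}
                )
            poolA = filtered.subset_samples(
                [s for s in analysis_samples
                 if meta.population_of(s) == config.pop_a]
            ).subset_loci(diagnostic_loci)
            poolB = filtered.subset_samples(
                [s for s in analysis_samples
                 if meta.population_of(s) == config.pop_b]
            ).subset_loci(diagnostic_loci)
            trajs = wf_simulator.run_simulation(sim_cfg, poolA, poolB)
            fixation = wf_simulator.fixation_summary(trajs)
            fixation.to_csv(out / "fixation_summary.csv", index=False)
            class_map = wf_simulator.derive_class_map(poolA, poolB)
            fa = {l: dict(freqs.get(config.pop_a, l).freqs) for l in diagnostic_loci}
            fb = {l: dict(freqs.get(config.pop_b, l).freqs) for l in diagnostic_loci}
            comp = wf_simulator.simulated_ancestry_composition(
                trajs, diagnostic_loci, class_map, fa, fb
            )
            comp.to_csv(out / "simulated_ancestry.csv", index=False)

        stage = "reports"
        write_structure_file(rep_table, out / "genotypes.str", meta)
        report_tables(out, table3, fst, hybrid_frame, fixation)
        for p in sorted(out.iterdir()):
            if p.is_file():
                manifest.setdefault("outputs", {})[p.name] = _sha256(p)
        manifest["completed"] = True
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    except Exception as exc:
        manifest["completed"] = False
        manifest["failed_stage"] = stage
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        config, out, rep_table, representatives, meta,
        fst=fst, diversity=diversity_frames, diagnostic_loci=diagnostic_loci,
        hybrid_indices=hybrid_frame, decision=decision, fixation=fixation,
        manifest=manifest,
    )


def _table3(
    diversity_frames: Mapping[str, pd.DataFrame], missing: pd.Series
) -> pd.DataFrame:
    """Per-locus diversity table across populations, one locus per row,
    with the locus missing rate in brackets after the locus name."""
    loci = list(missing.index)
    rows = []
    for locus in loci:
        row: dict[str, object] = {
            "locus": f"{locus} ({missing[locus] * 100:.1f}%)"
        }
        for pop, df in diversity_frames.items():
            sub = df.loc[df["locus"] == locus]
            if sub.empty:
                row[f"{pop}_He"] = np.nan
                continue
            rec = sub.iloc[0]
            row[f"{pop}_n"] = rec["n"]
            row[f"{pop}_He"] = rec["He"]
            row[f"{pop}_Ho"] = rec["Ho"]
            row[f"{pop}_p"] = rec["hwe_p"]
        rows.append(row)
    return pd.DataFrame(rows)


def _concatenated_sequences(
    genotypes: GenotypeTable, catalogs: Mapping[str, object]
) -> list[tuple[str, str]]:
    """Per-individual concatenated unphased sequences across loci, with
    IUPAC ambiguity codes at heterozygous sites and N-runs for missing
    genotypes (mirroring direct Sanger reads of the amplicons)."""
    out = []
    for i, sample in enumerate(genotypes.samples):
        parts = []
        for j, locus in enumerate(genotypes.loci):
            catalog = catalogs[locus]
            length = len(next(iter(catalog.code_of)))
            a, b = genotypes.alleles[i, j]
            if a < 0 or b < 0:
                parts.append("N" * length)
                continue
            parts.append(
                popgen_stats.consensus_with_iupac(
                    catalog.sequence_of(int(a)), catalog.sequence_of(int(b))
                )
            )
        out.append((sample, "".join(parts)))
    return out


def _markdown(df: pd.DataFrame, index: bool = False) -> str:
    """Minimal GitHub-table rendering (numbers to 4 significant places)."""
    def fmt(v: object) -> str:
        if isinstance(v, float):
            return "" if np.isnan(v) else f"{v:.4g}"
        return str(v)

    if index:
        df = df.reset_index()
    header = [str(c) for c in df.columns]
    rows = [[fmt(v) for v in rec] for rec in df.itertuples(index=False)]
    widths = [max(len(h), *(len(r[i]) for r in rows)) if rows else len(h)
              for i, h in enumerate(header)]
    def line(cells: list[str]) -> str:
        return "| " + " | ".join(c.ljust(w) for c, w in zip(cells, widths)) + " |"
    out = [line(header), line(["-" * w for w in widths])]
    out += [line(r) for r in rows]
    return "\n".join(out)


def report_tables(
    outdir: Path,
    table3: pd.DataFrame,
    fst: popgen_stats.FstMatrix | None,
    hybrid_frame: pd.DataFrame | None,
    fixation: pd.DataFrame | None,
) -> Path:
    """Markdown summary mirroring the CSV outputs."""
    lines = ["# Analysis report", "", "## Per-locus diversity", ""]
    lines.append(_markdown(table3))
    if fst is not None:
        lines += ["", "## Pairwise FST (point below diagonal, 95% CI above)", "",
                  _markdown(fst.to_frame(), index=True)]
    if hybrid_frame is not None:
        lines += ["", "## Hybrid index roster", "", _markdown(hybrid_frame)]
    if fixation is not None:
        lines += ["", "## Fixation timing", "", _markdown(fixation)]
    path = outdir / "report.md"
    path.write_text("\n".join(lines) + "\n")
    return path
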