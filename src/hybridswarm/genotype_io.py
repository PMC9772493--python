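"""Reading, writing and coding of multilocus Sanger genotype data.

The analysis starts from per-locus alignments of phased haplotype sequences
(two sequences per diploid individual per amplicon).  Identical sequences
within a locus are collapsed into integer-coded alleles, giving each
individual an unordered pair of allele codes per locus — the classic
"two-digit" coding consumed by STRUCTURE-style programs.  This module owns
those containers plus the sample-selection filters applied before any
statistics: the phasing-confidence discard rule and the ancestry-coefficient
(Q) representative filter.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

#: Sentinel for a missing allele copy.  Never 0: allele codes are 1-based.
MISSING: int = -1

#: Missing-data code used in the two-digit flat (STRUCTURE) format.
STRUCTURE_MISSING: str = "-9"

#: Default FASTA header dialect: ``>sampleID|locus|phase`` with phase 1 or 2.
DEFAULT_HEADER_REGEX = re.compile(
    r"^(?P<sample>[^|]+)\|(?P<locus>[^|]+)\|(?P<phase>[12])$"
)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class LocusAlignment:
    """Aligned phased haplotype sequences for one amplicon."""

    locus_name: str
    #: list of (sample_id, phase in {1, 2}, uppercase nucleotide string)
    sequences: list[tuple[str, int, str]]
    length: int

    def __post_init__(self) -> None:
        seen: set[tuple[str, int]] = set()
        for sample, phase, seq in self.sequences:
            if len(seq) != self.length:
                raise ValueError(
                    f"ragged alignment at locus {self.locus_name!r}: record "
                    f"({sample}, phase {phase}) has length {len(seq)}, "
                    f"expected {self.length}"
                )
            key = (sample, phase)
            if key in seen:
                raise ValueError(
                    f"duplicate record ({sample}, phase {phase}) at locus "
                    f"{self.locus_name!r}"
                )
            seen.add(key)


@dataclass
class HaplotypeCatalog:
    """Mapping from distinct haplotype sequence to 1-based allele code."""

    locus_name: str
    code_of: dict[str, int]

    def __post_init__(self) -> None:
        codes = sorted(self.code_of.values())
        if codes != list(range(1, len(codes) + 1)):
            raise ValueError("allele codes must be consecutive starting at 1")

    @property
    def n_alleles(self) -> int:
        return len(self.code_of)

    def sequence_of(self, code: int) -> str:
        for seq, c in self.code_of.items():
            if c == code:
                return seq
        raise KeyError(code)


def _canonical_pair(a: int, b: int) -> tuple[int, int]:
    """Order an unordered allele pair: non-missing ascending, missing last."""
    pair = sorted((int(a), int(b)), key=lambda x: (x == MISSING, x))
    return pair[0], pair[1]


@dataclass
class GenotypeTable:
    """Individuals x loci table of unordered allele-code pairs.

    ``alleles`` has shape (n_samples, n_loci, 2) with :data:`MISSING` for
    absent copies.  Pairs are stored in canonical order so that equality and
    round-tripping are well defined for unordered genotypes.
    """

    samples: list[str]
    loci: list[str]
    alleles: np.ndarray

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int32)
        if self.alleles.shape != (len(self.samples), len(self.loci), 2):
            raise ValueError(
                f"allele array shape {self.alleles.shape} does not match "
                f"{len(self.samples)} samples x {len(self.loci)} loci x 2"
            )
        # canonicalize unordered pairs: non-missing ascending, missing last
        key = np.where(self.alleles == MISSING, np.iinfo(np.int32).max, self.alleles)
        order = np.argsort(key, axis=2, kind="stable")
        self.alleles = np.take_along_axis(self.alleles, order, axis=2)

    # -- indexing helpers ---------------------------------------------------

    def sample_index(self, sample: str) -> int:
        return self.samples.index(sample)

    def locus_index(self, locus: str) -> int:
        return self.loci.index(locus)

    def genotype(self, sample: str, locus: str) -> tuple[int, int]:
        i, j = self.sample_index(sample), self.locus_index(locus)
        return tuple(self.alleles[i, j])

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeTable":
        idx = [self.sample_index(s) for s in samples]
        return GenotypeTable(list(samples), list(self.loci), self.alleles[idx].copy())

    def subset_loci(self, loci: Sequence[str]) -> "GenotypeTable":
        idx = [self.locus_index(l) for l in loci]
        return GenotypeTable(list(self.samples), list(loci), self.alleles[:, idx].copy())

    # -- missingness --------------------------------------------------------

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (samples x loci): True where the genotype is not fully
        called (either copy missing; half-missing counts as missing)."""
        return (self.alleles == MISSING).any(axis=2)

    def missing_rate(self, locus: str | None = None) -> float:
        """Proportion of missing genotype cells, overall or for one locus."""
        m = self.missing_mask
        if locus is not None:
            m = m[:, self.locus_index(locus)]
        return float(m.mean())

    def missing_report(self) -> pd.Series:
        """Per-locus missing-genotype rate, indexed by locus name."""
        return pd.Series(self.missing_mask.mean(axis=0), index=self.loci, name="missing_rate")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeTable):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.loci == other.loci
            and np.array_equal(self.alleles, other.alleles)
        )


@dataclass
class SampleMetadata:
    """Per-sample annotations: population, locality, coordinates, mtDNA."""

    table: pd.DataFrame
    populations: tuple[str, ...] = ()

    REQUIRED = ("sample_id", "population")
    OPTIONAL = ("locality", "lat", "lon", "mthap")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        for col in self.OPTIONAL:
            if col not in self.table.columns:
                self.table[col] = np.nan
        if not self.populations:
            self.populations = tuple(pd.unique(self.table["population"]))
        unknown = set(self.table["population"]) - set(self.populations)
        if unknown:
            raise ValueError(f"population labels outside declared set: {sorted(unknown)}")
        self.table = self.table.set_index("sample_id", drop=False)

    @classmethod
    def read_csv(cls, path: str | Path, populations: Sequence[str] = ()) -> "SampleMetadata":
        return cls(pd.read_csv(path, dtype={"sample_id": str}), tuple(populations))

    def write_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def population_of(self, sample: str) -> str:
        return str(self.table.loc[sample, "population"])

    def samples_in(self, population: str) -> list[str]:
        return list(self.table.loc[self.table["population"] == population, "sample_id"])

    @property
    def samples(self) -> list[str]:
        return list(self.table["sample_id"])


@dataclass
class QMatrix:
    """Ancestry-coefficient matrix from an upstream clustering run."""

    samples: list[str]
    Q: np.ndarray

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2 or self.Q.shape[0] != len(self.samples):
            raise ValueError("Q must be (n_samples, K)")
        if (self.Q < -1e-9).any() or (self.Q > 1 + 1e-9).any():
            raise ValueError("Q entries must lie in [0, 1]")
        sums = self.Q.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-3:
            bad = int(np.abs(sums - 1.0).argmax())
            raise ValueError(
                f"Q row for sample {self.samples[bad]!r} sums to {sums[bad]:.4f}, not 1"
            )
        self.Q = self.Q / sums[:, None]

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    def max_q(self, sample: str) -> float:
        return float(self.Q[self.samples.index(sample)].max())


# ---------------------------------------------------------------------------
# FASTA input and haplotype collapsing
# ---------------------------------------------------------------------------


def read_locus_fasta(
    path: str | Path,
    locus_name: str,
    header_regex: re.Pattern | str = DEFAULT_HEADER_REGEX,
) -> LocusAlignment:
    """Read one per-locus alignment of phased haplotypes from FASTA.

    Headers must match ``header_regex`` with named groups ``sample`` and
    ``phase`` (and optionally ``locus``).  The default dialect is
    ``>sampleID|locus|phase``.
    """
    if isinstance(header_regex, str):
        header_regex = re.compile(header_regex)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no records in FASTA {path}")
    sequences: list[tuple[str, int, str]] = []
    length = len(records[0].seq)
    for rec in records:
        m = header_regex.match(rec.id)
        if m is None:
            raise ValueError(f"FASTA header {rec.id!r} does not match the header dialect")
        if "locus" in m.groupdict() and m.group("locus") != locus_name:
            raise ValueError(
                f"record {rec.id!r} labelled locus {m.group('locus')!r}, "
                f"expected {locus_name!r}"
            )
        seq = str(rec.seq).upper()
        if len(seq) != length:
            raise ValueError(
                f"ragged alignment in {path}: record {rec.id!r} has length "
                f"{len(seq)}, expected {length}"
            )
        sequences.append((m.group("sample"), int(m.group("phase")), seq))
    return LocusAlignment(locus_name, sequences, length)


def collapse_haplotypes(
    aln: LocusAlignment,
) -> tuple[HaplotypeCatalog, dict[str, tuple[int, int]]]:
    """Collapse identical sequences into allele codes and build genotypes.

    Codes are assigned 1, 2, ... in order of first appearance in the
    alignment.  A sample with both phases present gets an unordered code
    pair; a sample with a single phase gets a half-missing genotype.
    """
    if not aln.sequences:
        raise ValueError("empty alignment")
    code_of: dict[str, int] = {}
    per_sample: dict[str, dict[int, int]] = {}
    for sample, phase, seq in aln.sequences:
        if seq not in code_of:
            code_of[seq] = len(code_of) + 1
        per_sample.setdefault(sample, {})[phase] = code_of[seq]
    genotypes = {
        sample: _canonical_pair(phases.get(1, MISSING), phases.get(2, MISSING))
        for sample, phases in per_sample.items()
    }
    return HaplotypeCatalog(aln.locus_name, code_of), genotypes


def genotypes_from_alignments(
    alignments: Sequence[LocusAlignment],
    samples: Sequence[str] | None = None,
) -> tuple[GenotypeTable, dict[str, HaplotypeCatalog]]:
    """Collapse a set of per-locus alignments into one genotype table.

    ``samples`` fixes the row order; by default, order of first appearance
    across alignments.  Samples absent from a locus are fully missing there.
    """
    catalogs: dict[str, HaplotypeCatalog] = {}
    per_locus: dict[str, dict[str, tuple[int, int]]] = {}
    if samples is None:
        ordered: list[str] = []
        seen: set[str] = set()
        for aln in alignments:
            for sample, _, _ in aln.sequences:
                if sample not in seen:
                    seen.add(sample)
                    ordered.append(sample)
        samples = ordered
    loci = [aln.locus_name for aln in alignments]
    for aln in alignments:
        catalog, genotypes = collapse_haplotypes(aln)
        catalogs[aln.locus_name] = catalog
        per_locus[aln.locus_name] = genotypes
    alleles = np.full((len(samples), len(loci), 2), MISSING, dtype=np.int32)
    for j, locus in enumerate(loci):
        for i, sample in enumerate(samples):
            if sample in per_locus[locus]:
                alleles[i, j] = per_locus[locus][sample]
    return GenotypeTable(list(samples), loci, alleles), catalogs


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def apply_phase_confidence_filter(
    genotypes: GenotypeTable,
    confidence: np.ndarray,
    threshold: float = 0.95,
) -> GenotypeTable:
    """Discard genotypes whose phasing posterior probability is below
    ``threshold`` (strictly: confidence < threshold is set to missing).

    ``confidence`` is (n_samples, n_loci) with entries in [0, 1].
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must be in (0, 1]")
    confidence = np.asarray(confidence, dtype=float)
    if confidence.shape != (len(genotypes.samples), len(genotypes.loci)):
        raise ValueError("confidence array must be (n_samples, n_loci)")
    if (confidence < 0).any() or (confidence > 1).any():
        raise ValueError("confidence values must lie in [0, 1]")
    alleles = genotypes.alleles.copy()
    alleles[confidence < threshold] = MISSING
    return GenotypeTable(list(genotypes.samples), list(genotypes.loci), alleles)


def filter_representatives(
    Q: QMatrix,
    threshold: float = 0.85,
    exclude: Iterable[str] = (),
) -> list[str]:
    """Samples whose maximum ancestry coefficient strictly exceeds
    ``threshold`` and that are not in the exclusion set (e.g. individuals
    forming a substructure in the clustering)."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must be in (0, 1)")
    excluded = set(exclude)
    return [
        s
        for s, row in zip(Q.samples, Q.Q)
        if s not in excluded and float(row.max()) > threshold
    ]


# ---------------------------------------------------------------------------
# Flat two-digit (STRUCTURE) format
# ---------------------------------------------------------------------------


def write_structure_file(
    genotypes: GenotypeTable,
    path: str | Path,
    meta: SampleMetadata | None = None,
) -> None:
    """Write the two-row-per-individual two-digit flat file.

    One row per phase; columns are sample id, optional population label,
    then one zero-padded two-digit allele code per locus; missing copies are
    written as ``-9``.  Allele codes above 99 violate the two-digit contract.
    """
    if (genotypes.alleles > 99).any():
        raise ValueError("allele code > 99 cannot be written in two-digit format")
    lines = [" ".join(["sample"] + (["pop"] if meta is not None else []) + genotypes.loci)]
    for i, sample in enumerate(genotypes.samples):
        prefix = [sample]
        if meta is not None:
            prefix.append(meta.population_of(sample))
        for k in range(2):
            cells = [
                STRUCTURE_MISSING if a == MISSING else f"{a:02d}"
                for a in genotypes.alleles[i, :, k]
            ]
            lines.append(" ".join(prefix + cells))
    Path(path).write_text("\n".join(lines) + "\n")


def read_structure_file(path: str | Path) -> GenotypeTable:
    """Read the flat file produced by :func:`write_structure_file`."""
    lines = [ln.split() for ln in Path(path).read_text().splitlines() if ln.strip()]
    header = lines[0]
    has_pop = len(header) > 1 and header[1] == "pop"
    loci = header[2:] if has_pop else header[1:]
    body = lines[1:]
    if len(body) % 2:
        raise ValueError("flat file must have two rows per individual")
    samples: list[str] = []
    rows: list[np.ndarray] = []
    ncol = 2 if has_pop else 1
    for r in range(0, len(body), 2):
        row1, row2 = body[r], body[r + 1]
        if row1[0] != row2[0]:
            raise ValueError(f"phase rows for {row1[0]!r}/{row2[0]!r} are not paired")
        samples.append(row1[0])
        a1 = [MISSING if c == STRUCTURE_MISSING else int(c) for c in row1[ncol:]]
        a2 = [MISSING if c == STRUCTURE_MISSING else int(c) for c in row2[ncol:]]
        if len(a1) != len(loci) or len(a2) != len(loci):
            raise ValueError(f"wrong number of locus columns for sample {row1[0]!r}")
        rows.append(np.stack([a1, a2], axis=1))
    return GenotypeTable(samples, list(loci), np.stack(rows, axis=0))


# ---------------------------------------------------------------------------
# Q-matrix input
# ---------------------------------------------------------------------------


def read_qmatrix(path: str | Path, samples: Sequence[str] | None = None) -> QMatrix:
    """Read a whitespace-delimited ancestry-coefficient matrix.

    Rows are either ``q1 q2 ... qK`` (then ``samples`` must be given or rows
    are numbered) or ``sample_id q1 ... qK``.
    """
    labels: list[str] = []
    rows: list[list[float]] = []
    for ln in Path(path).read_text().splitlines():
        parts = ln.split()
        if not parts or parts[0].startswith("#"):
            continue
        try:
            float(parts[0])
            label = None
            values = [float(p) for p in parts]
        except ValueError:
            label = parts[0]
            values = [float(p) for p in parts[1:]]
        labels.append(label if label is not None else str(len(rows) + 1))
        rows.append(values)
    if not rows:
        raise ValueError(f"no rows in Q matrix {path}")
    K = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != K:
            raise ValueError(f"Q row {i + 1} has {len(row)} columns, expected {K}")
    if samples is not None:
        if len(samples) != len(rows):
            raise ValueError("sample list length does not match Q rows")
        labels = list(samples)
    return QMatrix(labels, np.array(rows))


def write_qmatrix(Q: QMatrix, path: str | Path) -> None:
    lines = [
        s + " " + " ".join(f"{q:.6f}" for q in row) for s, row in zip(Q.samples, Q.Q)
    ]
    Path(path).write_text("\n".join(lines) + "\n")
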