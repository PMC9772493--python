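"""Shared fixtures: small hand-built tables and one full synthetic study.

The synthetic bundle and the pipeline run on it are session-scoped because
several test modules (including the acceptance tests) read from them; they
are generated once with a fixed seed so every assertion sees the same data.
"""

from __future__ import annotations

import numpy as np
import pytest

from hybridswarm import synthetic_data
from hybridswarm.genotype_io import MISSING, GenotypeTable, SampleMetadata
from hybridswarm.pipeline import PipelineConfig, run_pipeline

#: Master seed for all stochastic fixtures (kept below 2**31).
MASTER_SEED = 20240817


def make_table(pairs, samples=None, loci=None):
    """GenotypeTable from a nested list ``pairs[sample][locus] = (a, b)``."""
    arr = np.array(pairs, dtype=np.int32)
    n, L = arr.shape[0], arr.shape[1]
    samples = samples or [f"ind{i + 1}" for i in range(n)]
    loci = loci or [f"loc{j + 1}" for j in range(L)]
    return GenotypeTable(samples, loci, arr)


def make_meta(populations_of, **extra_cols):
    """SampleMetadata from a mapping sample -> population."""
    import pandas as pd

    rows = [{"sample_id": s, "population": p} for s, p in populations_of.items()]
    df = pd.DataFrame(rows)
    for col, values in extra_cols.items():
        df[col] = values
    return SampleMetadata(df)


@pytest.fixture()
def two_pop_table():
    """Two populations of 10 diploids, two identical biallelic loci with
    allele-1 frequencies 0.9 (P1) and 0.2 (P2) exactly."""
    p1 = [[(1, 1), (1, 1)]] * 8 + [[(1, 2), (1, 2)]] * 2       # 18/20 copies of 1
    p2 = [[(1, 2), (1, 2)]] * 4 + [[(2, 2), (2, 2)]] * 6       # 4/20 copies of 1
    table = make_table(p1 + p2)
    meta = make_meta({s: ("P1" if i < 10 else "P2")
                      for i, s in enumerate(table.samples)})
    return table, meta


@pytest.fixture(scope="session")
def study_design():
    return synthetic_data.SyntheticDesign(seed=MASTER_SEED)


@pytest.fixture(scope="session")
def study_bundle(tmp_path_factory, study_design):
    outdir = tmp_path_factory.mktemp("bundle")
    return synthetic_data.generate_study_bundle(study_design, outdir)


@pytest.fixture(scope="session")
def pipeline_config(tmp_path_factory, study_bundle, study_design):
    return PipelineConfig(
        loci_dir=str(study_bundle.loci_dir),
        metadata_csv=str(study_bundle.metadata_csv),
        qmatrix_file=str(study_bundle.qmatrix_file),
        output_dir=str(tmp_path_factory.mktemp("results")),
        populations=list(study_design.pop_sizes),
        seed=MASTER_SEED,
    )


@pytest.fixture(scope="session")
def pipeline_result(pipeline_config):
    return run_pipeline(pipeline_config)
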