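"""Shared fixtures: hand-built toy matrices and one default simulated run."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from hepatoseq.containers import CountMatrix
from hepatoseq.pipeline import PipelineConfig, run_all


def make_count_matrix(
    counts: np.ndarray,
    ercc_mask: list[bool] | None = None,
    lengths: list[float] | None = None,
    ploidy: list[str] | None = None,
    dilution: list[str] | None = None,
    plates: list[str] | None = None,
    tech_rep: list[bool] | None = None,
) -> CountMatrix:
    """Small CountMatrix with sensible metadata defaults."""
    counts = np.asarray(counts)
    n, m = counts.shape
    ercc_mask = ercc_mask if ercc_mask is not None else [False] * m
    ids = [
        f"ERCC-{j:05d}" if ercc_mask[j] else f"G{j:03d}" for j in range(m)
    ]
    features = pd.DataFrame(
        {
            "gene_name": ids,
            "is_ercc": ercc_mask,
            "length_kb": lengths if lengths is not None else [1.0] * m,
        },
        index=pd.Index(ids, name="feature_id"),
    )
    nuclei = pd.DataFrame(
        {
            "ploidy": ploidy if ploidy is not None else ["2n"] * n,
            "plate_id": plates if plates is not None else ["P1"] * n,
            "animal_id": ["A1"] * n,
            "dilution_group": dilution if dilution is not None else ["1:100000"] * n,
            "is_technical_replicate": tech_rep if tech_rep is not None else [False] * n,
        },
        index=pd.Index([f"N{i:03d}" for i in range(n)], name="nucleus_id"),
    )
    return CountMatrix(counts=counts, features=features, nuclei=nuclei)


@pytest.fixture(scope="session")
def default_run():
    """One full pipeline run on the default simulation (seed 1), shared
    across tests that probe planted structure."""
    return run_all(PipelineConfig(seed=1))


@pytest.fixture(scope="session")
def default_sim(default_run):
    return default_run.counts, default_run.truth
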