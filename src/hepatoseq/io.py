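"""Readers and writers for count matrices and reports.

Two on-disk layouts are supported, both plain text:

``mtx_dir``
    A directory with ``matrix.mtx`` (Matrix Market coordinate, integer,
    nuclei as rows), ``features.tsv`` and ``nuclei.tsv``.
``tsv``
    A directory with a dense ``counts.tsv`` (nuclei as rows, feature ids as
    columns) plus the same two sidecar tables.

ERCC spike-ins are recognized by an explicit boolean ``is_ercc`` column in
the feature table; if the column is absent, the feature-id prefix ``ERCC-``
is used instead.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from hepatoseq.containers import CountMatrix, FilterReport, NormalizedMatrix

ERCC_PREFIX = "ERCC-"


def _load_feature_table(path: Path) -> pd.DataFrame:
    feats = pd.read_csv(path, sep="\t", index_col=0)
    if "is_ercc" not in feats.columns:
        feats["is_ercc"] = feats.index.str.startswith(ERCC_PREFIX)
    else:
        feats["is_ercc"] = feats["is_ercc"].astype(bool)
    if "gene_name" not in feats.columns:
        feats["gene_name"] = feats.index
    return feats


def read_count_matrix(path: str | Path, format: str = "mtx_dir") -> CountMatrix:
    """Read a validated :class:`CountMatrix` from ``path``.

    Raises ``ValueError`` on dimension mismatches, negative or non-integer
    entries, and duplicate ids (via CountMatrix validation).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "mtx_dir":
        mat = scipy.io.mmread(path / "matrix.mtx")
        counts = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    elif format == "tsv":
        counts_df = pd.read_csv(path / "counts.tsv", sep="\t", index_col=0)
        counts = counts_df.to_numpy()
    else:
        raise ValueError(f"unknown format {format!r}; use 'mtx_dir' or 'tsv'")
    if counts.size and counts.min() < 0:
        raise ValueError("count file contains negative entries")
    if not np.all(np.equal(np.mod(counts, 1), 0)):
        raise ValueError("count file contains non-integer entries")
    features = _load_feature_table(path / "features.tsv")
    nuclei = pd.read_csv(path / "nuclei.tsv", sep="\t", index_col=0)
    nuclei["is_technical_replicate"] = nuclei["is_technical_replicate"].astype(bool)
    if format == "tsv":
        # align sidecars to the dense table's own labels
        features = features.loc[counts_df.columns]
        nuclei = nuclei.loc[counts_df.index]
    features.index.name = "feature_id"
    nuclei.index.name = "nucleus_id"
    return CountMatrix(counts=counts.astype(np.int64), features=features, nuclei=nuclei)


def write_count_matrix(cm: CountMatrix, path: str | Path, format: str = "mtx_dir") -> Path:
    """Write ``cm`` under directory ``path`` in the given layout."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    if format == "mtx_dir":
        scipy.io.mmwrite(
            str(path / "matrix.mtx"), scipy.sparse.coo_matrix(cm.counts), field="integer"
        )
    elif format == "tsv":
        pd.DataFrame(
            cm.counts, index=cm.nuclei.index, columns=cm.features.index
        ).to_csv(path / "counts.tsv", sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
    cm.features.to_csv(path / "features.tsv", sep="\t")
    cm.nuclei.to_csv(path / "nuclei.tsv", sep="\t")
    return path


def write_normalized_matrix(nm: NormalizedMatrix, path: str | Path) -> Path:
    """Write normalized values as TSV plus a JSON provenance sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(nm.values, index=nm.nuclei.index, columns=nm.genes.index).to_csv(
        path / "normalized.tsv", sep="\t"
    )
    nm.genes.to_csv(path / "genes.tsv", sep="\t")
    nm.nuclei.to_csv(path / "nuclei.tsv", sep="\t")
    sidecar = {
        "scale_constant": nm.scale_constant,
        "is_log": nm.is_log,
        "is_batch_corrected": nm.is_batch_corrected,
        "size_factors": nm.size_factors.table["sf"].to_dict(),
        "dilution_groups": nm.size_factors.table["dilution_group"].astype(str).to_dict(),
    }
    (path / "provenance.json").write_text(json.dumps(sidecar, indent=2))
    return path


def write_filter_report(report: FilterReport, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(report.to_json())
    path.with_suffix(".txt").write_text(str(report) + "\n")
    return path
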