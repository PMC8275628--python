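"""Binary co-expression analysis of stem/progenitor markers.

Log-normalized expression is binarized (detected / not detected), restricted
to a marker panel, and nuclei expressing none of the markers are dropped.
Pairwise co-detection between markers is quantified by the Jaccard index

    J(X, Y) = |X n Y| / |X u Y|

over the sets of nuclei in which each marker is detected; 1 - J is the
Jaccard distance used for average-linkage hierarchical clustering, and
modules are flat clusters obtained by cutting the tree at a distance
threshold.  Expression level is deliberately ignored: only presence/absence
per nucleus counts, so lowly and highly expressed markers contribute equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

from hepatoseq.containers import NormalizedMatrix


@dataclass
class BinaryMatrix:
    """Nuclei x markers detection matrix with entries in {0, 1}."""

    values: pd.DataFrame  # index nucleus_id, columns marker names, dtype int8

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("binary matrix entries must be 0 or 1")
        self.values = self.values.astype(np.int8)


def binarize(nm: NormalizedMatrix) -> BinaryMatrix:
    """1 where log-normalized expression is positive, else 0."""
    if not nm.is_log:
        raise ValueError("binarize expects log-transformed values")
    values = (nm.values > 0).astype(np.int8)
    return BinaryMatrix(pd.DataFrame(values, index=nm.nuclei.index, columns=nm.gene_names))


def subset_markers_drop_empty(bm: BinaryMatrix, markers: list[str]) -> BinaryMatrix:
    """Restrict to the marker panel and drop nuclei expressing none of them.

    Markers absent from the matrix are dropped with a warning; an empty
    resolved panel is an error.
    """
    present = [m for m in markers if m in bm.values.columns]
    missing = sorted(set(markers) - set(present))
    if missing:
        warnings.warn(f"markers not in matrix, dropped: {missing}", stacklevel=2)
    if not present:
        raise ValueError("none of the requested markers are present in the matrix")
    sub = bm.values[present]
    keep = sub.sum(axis=1) > 0
    return BinaryMatrix(sub.loc[keep].copy())


@dataclass
class JaccardResult:
    """Pairwise Jaccard similarity/distance between markers plus the linkage tree."""

    similarity: pd.DataFrame
    distance: pd.DataFrame
    linkage: np.ndarray
    linkage_method: str


def pairwise_jaccard(bm: BinaryMatrix, linkage_method: str = "average") -> JaccardResult:
    """Jaccard similarity over nucleus detection sets, per marker pair.

    A marker detected in zero retained nuclei has J = 0 against every other
    marker (and J = 1 with itself by convention); a warning is emitted.
    """
    x = bm.values.to_numpy(dtype=np.int64)
    if x.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    totals = x.sum(axis=0)
    if np.any(totals == 0):
        empty = bm.values.columns[totals == 0].tolist()
        warnings.warn(f"markers detected in zero nuclei: {empty}", stacklevel=2)
    inter = x.T @ x
    union = totals[:, None] + totals[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    np.fill_diagonal(sim, 1.0)
    markers = bm.values.columns
    similarity = pd.DataFrame(sim, index=markers, columns=markers)
    distance = 1.0 - similarity
    condensed = ssd.squareform(distance.to_numpy(), checks=False)
    linkage = sch.linkage(condensed, method=linkage_method)
    return JaccardResult(similarity, distance, linkage, linkage_method)


def extract_modules(jr: JaccardResult, distance_threshold: float = 0.5) -> list[list[str]]:
    """Flat modules (size >= 2) from cutting the linkage tree at a distance."""
    labels = sch.fcluster(jr.linkage, t=distance_threshold, criterion="distance")
    markers = jr.similarity.index
    modules = []
    for lab in np.unique(labels):
        members = sorted(markers[labels == lab].tolist())
        if len(members) >= 2:
            modules.append(members)
    modules.sort(key=lambda m: (-len(m), m))
    return modules


def coexpression_counts(
    bm: BinaryMatrix, ploidy: pd.Series, min_markers: int = 2
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-ploidy co-expression summary.

    Returns ``(summary, per_marker)`` where ``summary`` has, per ploidy
    level, the number of nuclei and the fraction co-expressing at least
    ``min_markers`` markers (NaN for an empty group), and ``per_marker`` the
    fraction of nuclei in which each marker is detected, per ploidy.
    """
    ploidy = ploidy.loc[bm.values.index]
    n_pos = bm.values.sum(axis=1)
    rows, marker_rows = [], []
    # observed=False keeps empty categorical levels: their fraction is NaN
    for level, idx in ploidy.groupby(ploidy, observed=False).groups.items():
        sub = bm.values.loc[idx]
        n = len(sub)
        frac = float((n_pos.loc[idx] >= min_markers).mean()) if n else float("nan")
        rows.append({"ploidy": level, "n_nuclei": n, f"frac_ge_{min_markers}_markers": frac})
        marker_rows.append(pd.Series(sub.mean(axis=0), name=level))
    summary = pd.DataFrame(rows).set_index("ploidy")
    per_marker = pd.DataFrame(marker_rows)
    per_marker.index.name = "ploidy"
    return summary, per_marker
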