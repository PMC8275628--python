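"""Embedding, graph clustering, and marker-panel cell-type annotation.

Nuclei are embedded by PCA on log-normalized expression, connected in a
k-nearest-neighbour graph (Euclidean distance in PC space), and partitioned
by modularity-based community detection (Leiden).  Clusters are then labeled
by marker panels: for each cluster the z-scored mean expression of each
panel's markers is computed, and the cluster takes the label of the panel
with the maximal score (ties are left "unassigned").
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd

from hepatoseq.containers import NormalizedMatrix

UNASSIGNED = "unassigned"


@dataclass
class ClusterAssignment:
    """Per-nucleus cluster ids with optional cell-type labels."""

    table: pd.DataFrame  # index nucleus_id; columns cluster, cell_type
    resolution: float

    @property
    def cluster(self) -> pd.Series:
        return self.table["cluster"]

    @property
    def cell_type(self) -> pd.Series:
        return self.table["cell_type"]


def _leiden(
    X: np.ndarray, n_pcs: int, k_neighbors: int, resolution: float, seed: int
) -> np.ndarray:
    """PCA -> kNN graph -> Leiden labels (ints), deterministic for a seed."""
    import scanpy as sc

    adata = ad.AnnData(X=np.asarray(X, dtype=np.float32))
    n_comps = int(min(n_pcs, X.shape[0] - 1, X.shape[1] - 1))
    if n_comps >= 2:
        sc.pp.pca(adata, n_comps=n_comps, random_state=seed)
        rep = "X_pca"
    else:
        rep = "X"
    sc.pp.neighbors(adata, n_neighbors=k_neighbors, use_rep=rep, random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="leidenalg",
            key_added="leiden",
        )
    return adata.obs["leiden"].astype(int).to_numpy()


def embed_and_cluster(
    nm: NormalizedMatrix,
    n_pcs: int = 50,
    k_neighbors: int = 15,
    resolution: float = 1.0,
    seed: int = 0,
) -> ClusterAssignment:
    """Cluster nuclei on the full log-normalized expression matrix."""
    if not nm.is_log:
        raise ValueError("clustering expects log-transformed values")
    if nm.n_nuclei <= k_neighbors:
        raise ValueError(f"need more than k_neighbors={k_neighbors} nuclei, have {nm.n_nuclei}")
    # degenerate input: identical rows carry no structure
    if np.allclose(nm.values, nm.values[0], atol=1e-12):
        labels = np.zeros(nm.n_nuclei, dtype=int)
    else:
        labels = _leiden(nm.values, n_pcs, k_neighbors, resolution, seed)
    table = pd.DataFrame(
        {"cluster": labels, "cell_type": UNASSIGNED}, index=nm.nuclei.index
    )
    return ClusterAssignment(table=table, resolution=resolution)


def annotate_clusters(
    ca: ClusterAssignment, nm: NormalizedMatrix, panel: dict[str, list[str]]
) -> ClusterAssignment:
    """Label clusters by their maximal z-scored mean marker-panel expression.

    ``panel`` maps cell-type label -> marker gene names.  Panel genes missing
    from the matrix are dropped with a warning; a panel losing all its genes
    is skipped.  Ties between best panels leave a cluster "unassigned".
    """
    if not panel:
        raise ValueError("empty marker panel")
    gene_lookup = pd.Index(nm.gene_names)
    resolved: dict[str, np.ndarray] = {}
    for label, genes in panel.items():
        pos = gene_lookup.get_indexer(genes)
        if np.any(pos < 0):
            missing = [g for g, p in zip(genes, pos) if p < 0]
            warnings.warn(f"panel {label!r}: genes missing from matrix, dropped: {missing}", stacklevel=2)
        pos = pos[pos >= 0]
        if len(pos):
            resolved[label] = pos
    if not resolved:
        raise ValueError("no panel gene is present in the matrix")

    # z-score each gene across nuclei so abundant genes do not dominate
    x = nm.values
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    z = (x - mu) / np.where(sd > 0, sd, 1.0)

    table = ca.table.copy()
    for cluster_id in np.unique(ca.cluster.to_numpy()):
        in_cluster = (ca.cluster == cluster_id).to_numpy()
        scores = {lab: float(z[np.ix_(in_cluster, pos)].mean()) for lab, pos in resolved.items()}
        ordered = sorted(scores.items(), key=lambda kv: kv[1], reverse=True)
        if len(ordered) > 1 and np.isclose(ordered[0][1], ordered[1][1]):
            warnings.warn(
                f"cluster {cluster_id}: tied marker scores, left {UNASSIGNED!r}", stacklevel=2
            )
            label = UNASSIGNED
        else:
            label = ordered[0][0]
        table.loc[in_cluster, "cell_type"] = label
    return ClusterAssignment(table=table, resolution=ca.resolution)


def subset_hepatocytes(
    nm: NormalizedMatrix, ca: ClusterAssignment, label: str = "hepatocyte"
) -> NormalizedMatrix:
    """Restrict the matrix to nuclei in clusters annotated as hepatocytes."""
    mask = (ca.cell_type == label).to_numpy()
    if not mask.any():
        raise ValueError(f"no cluster annotated as {label!r}")
    return nm.subset_nuclei(mask)
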