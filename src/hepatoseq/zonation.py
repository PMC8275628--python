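"""Pseudospatial zonation analysis of the hepatocyte compartment.

Hepatocytes are positioned along the pericentral (CV, central vein) to
periportal (PV, portal vein) axis of the liver lobule using a small panel of
zonation marker genes: community detection on the marker-restricted
expression space yields zone clusters, each cluster is annotated CV or PV by
comparing z-scored pericentral vs periportal marker scores, and diffusion
pseudotime from the most pericentral nucleus provides a continuous
pseudospace coordinate in [0, 1] oriented CV -> PV.  On top of this ordering
the module computes ploidy enrichment in the pericentral zone, binned
expression profiles, and CV/PV differential expression stratified by ploidy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd

from hepatoseq.containers import NormalizedMatrix
from hepatoseq.ploidy import welch_de


@dataclass
class ZonationMarkerPanel:
    """Pericentral / periportal / non-zonated marker gene lists (disjoint)."""

    pericentral: list[str]
    periportal: list[str]
    non_zonated: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.pericentral or not self.periportal:
            raise ValueError("pericentral and periportal lists must be non-empty")
        sets = [set(self.pericentral), set(self.periportal), set(self.non_zonated)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("zonation panel lists must be disjoint")

    @property
    def zonated(self) -> list[str]:
        return list(self.pericentral) + list(self.periportal)


def _marker_positions(nm: NormalizedMatrix, genes: list[str]) -> np.ndarray:
    lookup = pd.Index(nm.gene_names)
    pos = lookup.get_indexer(genes)
    if np.any(pos < 0):
        missing = [g for g, p in zip(genes, pos) if p < 0]
        warnings.warn(f"zonation markers missing from matrix, dropped: {missing}", stacklevel=2)
    pos = pos[pos >= 0]
    if len(pos) == 0:
        raise ValueError("no zonation marker present in the matrix")
    return pos


def _zscore(x: np.ndarray) -> np.ndarray:
    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    return (x - mu) / np.where(sd > 0, sd, 1.0)


def _marker_score(nm: NormalizedMatrix, genes: list[str]) -> np.ndarray:
    """Per-nucleus mean z-scored expression of a marker list."""
    pos = _marker_positions(nm, genes)
    return _zscore(nm.values[:, pos]).mean(axis=1)


def cluster_zonation_markers(
    nm_hep: NormalizedMatrix,
    panel: ZonationMarkerPanel,
    n_clusters: int = 3,
    k_neighbors: int = 15,
    seed: int = 0,
) -> pd.Series:
    """Community detection on the zonation-marker expression space.

    The Leiden resolution is searched (bisection on [0.01, 4]) for a
    partition with exactly ``n_clusters`` communities; if none is found,
    k-means with ``n_clusters`` is used as a k-constrained fallback.
    Constant marker expression yields a single cluster with a warning.
    """
    if nm_hep.n_nuclei < 3:
        raise ValueError("need at least 3 nuclei")
    pos = _marker_positions(nm_hep, panel.zonated)
    x = nm_hep.values[:, pos]
    if np.allclose(x, x[0], atol=1e-12):
        warnings.warn("constant marker expression: returning a single zone cluster", stacklevel=2)
        return pd.Series(np.zeros(nm_hep.n_nuclei, dtype=int), index=nm_hep.nuclei.index, name="zone_cluster")

    import scanpy as sc

    adata = ad.AnnData(X=np.asarray(x, dtype=np.float32))
    sc.pp.neighbors(adata, n_neighbors=min(k_neighbors, nm_hep.n_nuclei - 1), use_rep="X", random_state=seed)

    def run(res: float) -> np.ndarray:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.tl.leiden(adata, resolution=res, random_state=seed, flavor="leidenalg", key_added="zl")
        return adata.obs["zl"].astype(int).to_numpy()

    lo, hi = 0.01, 4.0
    labels = None
    for _ in range(25):
        mid = 0.5 * (lo + hi)
        cand = run(mid)
        k = len(np.unique(cand))
        if k == n_clusters:
            labels = cand
            break
        if k < n_clusters:
            lo = mid
        else:
            hi = mid
    if labels is None:
        from sklearn.cluster import KMeans

        labels = KMeans(n_clusters=n_clusters, n_init=10, random_state=seed).fit_predict(x)
    return pd.Series(labels, index=nm_hep.nuclei.index, name="zone_cluster")


def annotate_cv_pv(
    zone_clusters: pd.Series, nm: NormalizedMatrix, panel: ZonationMarkerPanel
) -> pd.Series:
    """Assign each zone cluster to CV or PV by its dominant marker score.

    A cluster is CV when its mean z-scored pericentral-marker expression
    exceeds the periportal score, PV otherwise; exact ties are an error.
    """
    cv_score = _marker_score(nm, panel.pericentral)
    pv_score = _marker_score(nm, panel.periportal)
    zone = pd.Series(index=zone_clusters.index, dtype=object, name="zone")
    for cluster_id in np.unique(zone_clusters.to_numpy()):
        in_cluster = (zone_clusters == cluster_id).to_numpy()
        s_cv, s_pv = cv_score[in_cluster].mean(), pv_score[in_cluster].mean()
        if np.isclose(s_cv, s_pv, atol=1e-12):
            raise ValueError(f"zone cluster {cluster_id} has tied CV/PV marker scores")
        zone[in_cluster] = "CV" if s_cv > s_pv else "PV"
    return zone


def diffusion_pseudospace(
    nm_hep: NormalizedMatrix,
    panel: ZonationMarkerPanel,
    k_neighbors: int = 15,
    seed: int = 0,
    root: str = "pericentral",
) -> pd.Series:
    """Diffusion-pseudotime coordinate on the zonation-marker space.

    A kNN graph with Gaussian-kernel connectivities is built on the z-scored
    marker-restricted log expression, the diffusion map is computed, and
    pseudotime is measured from a root nucleus at the pericentral extreme.
    The root is found on the denoised manifold: the leading diffusion
    component is oriented by its correlation with the pericentral-minus-
    periportal marker score and the nucleus at its pericentral end is the
    root (rooting directly on the noisy per-nucleus marker score is fragile:
    a mid-lobule outlier root folds the ordering).  ``root="periportal"``
    reverses the orientation.  The result is rescaled to [0, 1]; 0 is the
    root (CV) end.
    """
    pos = _marker_positions(nm_hep, panel.zonated)
    x = _zscore(np.asarray(nm_hep.values[:, pos], dtype=np.float64))
    if root not in ("pericentral", "periportal"):
        raise ValueError("root must be 'pericentral' or 'periportal'")
    score = _marker_score(nm_hep, panel.pericentral) - _marker_score(nm_hep, panel.periportal)
    if root == "periportal":
        score = -score

    import scanpy as sc

    adata = ad.AnnData(X=x)
    sc.pp.neighbors(adata, n_neighbors=min(k_neighbors, nm_hep.n_nuclei - 1), use_rep="X", random_state=seed)
    # a disconnected graph makes diffusion distances meaningless
    import scipy.sparse.csgraph as csgraph

    n_comp, _ = csgraph.connected_components(adata.obsp["connectivities"], directed=False)
    if n_comp > 1:
        raise ValueError(
            f"kNN graph has {n_comp} connected components; increase k_neighbors"
        )
    sc.tl.diffmap(adata)
    dc1 = np.asarray(adata.obsm["X_diffmap"][:, 1], dtype=float)
    if np.corrcoef(dc1, score)[0, 1] < 0:
        dc1 = -dc1
    adata.uns["iroot"] = int(np.argmax(dc1))
    sc.tl.dpt(adata)
    dpt = np.asarray(adata.obs["dpt_pseudotime"], dtype=float)
    rng = dpt.max() - dpt.min()
    if rng > 0:
        dpt = (dpt - dpt.min()) / rng
    return pd.Series(dpt, index=nm_hep.nuclei.index, name="dpt")


@dataclass
class ZonationAssignment:
    """Zone cluster, CV/PV zone, pseudospace and bin per hepatocyte nucleus."""

    table: pd.DataFrame  # columns zone_cluster, zone, dpt, bin

    @property
    def zone(self) -> pd.Series:
        return self.table["zone"]

    @property
    def dpt(self) -> pd.Series:
        return self.table["dpt"]


def assign_zonation(
    nm_hep: NormalizedMatrix,
    panel: ZonationMarkerPanel,
    n_clusters: int = 3,
    k_neighbors: int = 15,
    n_bins: int = 10,
    seed: int = 0,
) -> ZonationAssignment:
    """Run the full zonation assignment: clusters, zones, pseudospace, bins."""
    clusters = cluster_zonation_markers(nm_hep, panel, n_clusters=n_clusters, k_neighbors=k_neighbors, seed=seed)
    zone = annotate_cv_pv(clusters, nm_hep, panel)
    dpt = diffusion_pseudospace(nm_hep, panel, k_neighbors=k_neighbors, seed=seed)
    bins = bin_pseudospace(dpt, n_bins=n_bins)
    table = pd.DataFrame(
        {"zone_cluster": clusters, "zone": zone, "dpt": dpt, "bin": bins}
    )
    return ZonationAssignment(table=table)


def bin_pseudospace(dpt: pd.Series, n_bins: int = 10) -> pd.Series:
    """Equal-width bins (1..n_bins) over the [0, 1] pseudospace."""
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(dpt.to_numpy(), edges[1:-1], right=False) + 1, 1, n_bins)
    return pd.Series(idx, index=dpt.index, name="bin")


def ploidy_enrichment(
    za: ZonationAssignment,
    ploidy: pd.Series,
    enriched_ploidy: str = "4n",
    reference_ploidy: str = "2n",
    zone: str = "CV",
    mode: str = "ratio_of_fractions",
) -> float:
    """Relative enrichment of one ploidy class in a zone.

    ``ratio_of_fractions`` (default): the fraction of all ``enriched_ploidy``
    nuclei assigned to ``zone`` divided by the same fraction for
    ``reference_ploidy``.  ``vs_overall``: the enriched ploidy's zone
    fraction divided by the zone fraction over all nuclei.
    """
    ploidy = ploidy.loc[za.table.index]
    in_zone = (za.zone == zone).to_numpy()
    if not in_zone.any():
        raise ValueError(f"no nuclei assigned to zone {zone!r}")

    def zone_fraction(mask: np.ndarray) -> float:
        if not mask.any():
            raise ValueError("empty ploidy group")
        return float(in_zone[mask].mean())

    frac_enriched = zone_fraction((ploidy == enriched_ploidy).to_numpy())
    if mode == "ratio_of_fractions":
        denom = zone_fraction((ploidy == reference_ploidy).to_numpy())
    elif mode == "vs_overall":
        denom = float(in_zone.mean())
    else:
        raise ValueError("mode must be 'ratio_of_fractions' or 'vs_overall'")
    if denom == 0:
        raise ValueError("reference zone fraction is zero")
    return frac_enriched / denom


def bin_profiles(
    za: ZonationAssignment, nm: NormalizedMatrix, genes: list[str], n_bins: int = 10
) -> pd.DataFrame:
    """Per-gene mean log expression along pseudospace bins (NaN for empty bins)."""
    pos = _marker_positions(nm, genes)
    names = [nm.gene_names[p] for p in pos]
    bins = bin_pseudospace(za.dpt, n_bins=n_bins)
    out = pd.DataFrame(index=pd.RangeIndex(1, n_bins + 1, name="bin"), columns=names, dtype=float)
    for b in out.index:
        mask = (bins == b).to_numpy()
        if mask.any():
            out.loc[b] = nm.values[np.ix_(mask, pos)].mean(axis=0)
    return out


@dataclass
class ZonationDEByPloidy:
    """CV-vs-PV differential expression stratified by ploidy."""

    cv_up_all: pd.Index
    pv_up_all: pd.Index
    cv_up_only_enriched: pd.Index  # CV-up overall, significant only in the enriched (4n) stratum
    pv_up_only_reference: pd.Index  # PV-up overall, significant only in the reference (2n) stratum

    def counts(self) -> dict:
        return {
            "cv_up_all": len(self.cv_up_all),
            "cv_up_only_4n": len(self.cv_up_only_enriched),
            "pv_up_all": len(self.pv_up_all),
            "pv_up_only_2n": len(self.pv_up_only_reference),
        }


def zonation_de_by_ploidy(
    nm_hep: NormalizedMatrix,
    za: ZonationAssignment,
    ploidy: pd.Series,
    enriched_ploidy: str = "4n",
    reference_ploidy: str = "2n",
    min_group: int = 10,
) -> ZonationDEByPloidy:
    """Intersect CV/PV marker calls across ploidy strata.

    CV-vs-PV Welch DE (study call rules) is run on all hepatocytes and on
    each ploidy stratum separately.  "Zonation markers" are the significant
    CV-up / PV-up gene sets from the all-hepatocyte contrast; of these, the
    genes significant in one stratum but not the other are reported as
    ploidy-restricted.  Strata below ``min_group`` nuclei per zone are
    skipped with a warning (their restricted sets are then empty).
    """
    ploidy = ploidy.loc[za.table.index]
    cv_mask = (za.zone == "CV").to_numpy()
    pv_mask = (za.zone == "PV").to_numpy()

    def de_calls(sub_mask: np.ndarray) -> tuple[pd.Index, pd.Index] | None:
        cv, pv = cv_mask & sub_mask, pv_mask & sub_mask
        if cv.sum() < min_group or pv.sum() < min_group:
            return None
        de = welch_de(nm_hep, cv, pv)
        return de.index[de["call"] == "up"], de.index[de["call"] == "down"]

    overall = de_calls(np.ones(len(ploidy), dtype=bool))
    if overall is None:
        raise ValueError("too few nuclei per zone for the overall CV-vs-PV contrast")
    cv_up_all, pv_up_all = overall

    strata: dict[str, tuple[pd.Index, pd.Index] | None] = {}
    for level in (enriched_ploidy, reference_ploidy):
        calls = de_calls((ploidy == level).to_numpy())
        if calls is None:
            warnings.warn(f"ploidy stratum {level!r} below minimum group size; skipped", stacklevel=2)
        strata[level] = calls

    def only_in(target: str, other: str, universe: pd.Index, direction: int) -> pd.Index:
        if strata[target] is None:
            return pd.Index([])
        t_set = set(strata[target][direction])
        o_set = set(strata[other][direction]) if strata[other] is not None else set()
        return pd.Index([g for g in universe if g in t_set and g not in o_set])

    return ZonationDEByPloidy(
        cv_up_all=cv_up_all,
        pv_up_all=pv_up_all,
        cv_up_only_enriched=only_in(enriched_ploidy, reference_ploidy, cv_up_all, 0),
        pv_up_only_reference=only_in(reference_ploidy, enriched_ploidy, pv_up_all, 1),
    )
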