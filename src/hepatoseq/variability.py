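"""Per-gene transcriptional variability and HVG counting.

Variability is measured per gene within a ploidy group as the coefficient of
variation of log-transformed expression (sample standard deviation over
mean).  Group-level comparisons report the ratio of median CVs and a
two-sided Mann-Whitney U test across the shared gene set.  Highly variable
genes are selected by a mean-variance trend residual rule: a quadratic trend
of variance against mean is fitted across genes and the genes in the top
fraction of positive residuals are called HVGs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from hepatoseq.containers import NormalizedMatrix


def gene_cv(nm: NormalizedMatrix, mask: np.ndarray, ddof: int = 1) -> pd.Series:
    """Coefficient of variation (sd/mean of log values) per gene in a group.

    Genes with zero mean in the group are excluded from the result.
    """
    if not nm.is_log:
        raise ValueError("gene_cv expects log-transformed values")
    mask = np.asarray(mask, dtype=bool)
    if mask.sum() < 3:
        raise ValueError("group must contain at least 3 nuclei")
    x = nm.values[mask]
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=ddof)
    keep = mean > 0
    cv = sd[keep] / mean[keep]
    return pd.Series(cv, index=nm.gene_names[keep], name="cv")


@dataclass
class VariabilityResult:
    """CV comparison between two groups over their shared gene set."""

    cv_a: pd.Series
    cv_b: pd.Series
    ratio_of_medians: float  # median(cv_a) / median(cv_b)
    mw_p: float              # two-sided Mann-Whitney U p across genes


def cv_compare(nm: NormalizedMatrix, mask_a: np.ndarray, mask_b: np.ndarray) -> VariabilityResult:
    """Compare per-gene CV distributions between two groups of nuclei.

    CVs are computed on the genes expressed in both groups; the ratio of
    medians is a / b (for the study's contrast, a = 2n and b = 4n, so a ratio
    above 1 means the diploid group is more variable).  The Mann-Whitney p is
    exact for small gene sets and asymptotic otherwise (scipy's default).
    """
    cv_a = gene_cv(nm, mask_a)
    cv_b = gene_cv(nm, mask_b)
    shared = cv_a.index.intersection(cv_b.index)
    if len(shared) == 0:
        raise ValueError("no shared expressed genes between the groups")
    a = cv_a.loc[shared]
    b = cv_b.loc[shared]
    mw = scipy.stats.mannwhitneyu(a, b, alternative="two-sided")
    return VariabilityResult(
        cv_a=a,
        cv_b=b,
        ratio_of_medians=float(np.median(a) / np.median(b)),
        mw_p=float(mw.pvalue),
    )


def select_hvgs(
    nm: NormalizedMatrix, mask: np.ndarray, top_fraction: float = 0.10, n_bins: int = 20
) -> pd.Index:
    """Mean-variance trend residual HVG selection within a group.

    Per-gene dispersion (variance over mean of the log values) is compared
    against genes of similar abundance: genes are grouped into ``n_bins``
    mean-quantile bins, dispersions are z-scored within each bin, and the
    genes in the top ``top_fraction`` of positive z-scores are returned.
    Binning removes the strong mean-dispersion trend that would otherwise
    make raw residuals incomparable across the abundance range.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    mask = np.asarray(mask, dtype=bool)
    x = nm.values[mask]
    mean = x.mean(axis=0)
    var = x.var(axis=0, ddof=1)
    if np.all(var == 0):
        return pd.Index([])
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-12), 0.0)
    bins = pd.qcut(mean, q=min(n_bins, len(mean)), labels=False, duplicates="drop")
    z = np.zeros_like(disp)
    for b in np.unique(bins):
        sel = bins == b
        mu_b, sd_b = disp[sel].mean(), disp[sel].std(ddof=0)
        z[sel] = (disp[sel] - mu_b) / (sd_b if sd_b > 0 else 1.0)
    positive = np.where(z > 0)[0]
    n_top = max(1, int(round(top_fraction * len(positive))))
    top = positive[np.argsort(z[positive])[::-1][:n_top]]
    return pd.Index(nm.gene_names[np.sort(top)])


@dataclass
class HVGReport:
    """HVG sets per group and their overlap with the DE call set."""

    hvgs: pd.Index
    n_hvg: int
    n_hvg_non_de: int


def hvg_nonde_count(
    nm: NormalizedMatrix,
    mask: np.ndarray,
    de: pd.DataFrame | None = None,
    top_fraction: float = 0.10,
) -> HVGReport:
    """Count HVGs in a group, with and without DE-called genes removed.

    ``de`` is a table from :func:`hepatoseq.ploidy.welch_de`; genes whose
    call is ``up`` or ``down`` are considered DE.  With no DE table the
    non-DE count equals the raw HVG count.
    """
    hvgs = select_hvgs(nm, mask, top_fraction=top_fraction)
    if de is None:
        de_genes: set = set()
    else:
        de_genes = set(de.index[de["call"] != "ns"])
    n_non_de = len([g for g in hvgs if g not in de_genes])
    return HVGReport(hvgs=hvgs, n_hvg=len(hvgs), n_hvg_non_de=n_non_de)
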