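"""Ploidy contrasts: detection fold, Welch differential expression, KS shifts.

All contrasts are pairwise (2n vs 4n by default; higher ploidies reuse the
same operations).  Differential expression follows the rank-based Smart-seq
convention: Welch's unequal-variance t-test on log-normalized values, a
log2 fold change computed on expm1-back-transformed group means with a small
pseudo-count, Bonferroni adjustment, and a call rule of |log2FC| > 0.5 with
adjusted p < 0.05.  Distribution shifts are called by a per-gene two-sample
Kolmogorov-Smirnov test with p < 0.05 and D > 0.15.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from hepatoseq.containers import CountMatrix, NormalizedMatrix

#: pseudo-count used when back-transforming mean log expression for fold changes
LOG2FC_EPS = 1e-9


def detected_genes_fold(cm: CountMatrix, mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Ratio of median detected-gene counts, group b over group a.

    Detection is counted on the raw count matrix (endogenous genes with
    count > 0 per nucleus).  For the study's headline contrast, a = 2n and
    b = 4n, so values above 1 mean more genes detected per 4n nucleus.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if not mask_a.any() or not mask_b.any():
        raise ValueError("both groups must be non-empty")
    endo = cm.endogenous_counts
    n_a = np.median((endo[mask_a] > 0).sum(axis=1))
    n_b = np.median((endo[mask_b] > 0).sum(axis=1))
    if n_a == 0:
        raise ValueError("median detected genes in the reference group is zero")
    return float(n_b / n_a)


def _welch_t(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Welch t statistic and two-sided p per gene (columns)."""
    n1, n2 = a.shape[0], b.shape[0]
    m1, m2 = a.mean(axis=0), b.mean(axis=0)
    v1, v2 = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = v1 / n1 + v2 / n2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m2) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    # zero variance in both groups: t undefined -> no evidence, p = 1
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, 1.0, df)
    p = 2.0 * scipy.stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    return t, p


def welch_de(
    nm: NormalizedMatrix,
    mask_group: np.ndarray,
    mask_rest: np.ndarray,
    log2fc_threshold: float = 0.5,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Welch's t-test per gene, group vs rest, with the study's call rules.

    Returns a DataFrame indexed by gene name with columns ``mean_expr_group``,
    ``mean_expr_rest`` (mean log expression), ``mean_norm`` (mean of the
    back-transformed expression over both groups, for MA filtering),
    ``log2fc``, ``t_stat``, ``p``, ``p_bonferroni`` and ``call`` in
    {``up``, ``down``, ``ns``}.  ``up`` means higher in ``mask_group``.
    """
    if not nm.is_log:
        raise ValueError("welch_de expects log-transformed values")
    mask_group = np.asarray(mask_group, dtype=bool)
    mask_rest = np.asarray(mask_rest, dtype=bool)
    if mask_group.sum() < 2 or mask_rest.sum() < 2:
        raise ValueError("each group needs at least 2 nuclei")
    a = nm.values[mask_group]
    b = nm.values[mask_rest]
    t, p = _welch_t(a, b)
    n_tested = nm.values.shape[1]
    p_bonf = np.minimum(1.0, p * n_tested)
    m_group, m_rest = a.mean(axis=0), b.mean(axis=0)
    log2fc = np.log2((np.expm1(m_group) + LOG2FC_EPS) / (np.expm1(m_rest) + LOG2FC_EPS))
    both = np.concatenate([a, b], axis=0)
    mean_norm = np.expm1(both).mean(axis=0)
    call = np.where(
        (log2fc > log2fc_threshold) & (p_bonf < alpha),
        "up",
        np.where((log2fc < -log2fc_threshold) & (p_bonf < alpha), "down", "ns"),
    )
    return pd.DataFrame(
        {
            "mean_expr_group": m_group,
            "mean_expr_rest": m_rest,
            "mean_norm": mean_norm,
            "log2fc": log2fc,
            "t_stat": t,
            "p": p,
            "p_bonferroni": p_bonf,
            "call": call,
        },
        index=nm.gene_names,
    )


def ks_shift(
    nm: NormalizedMatrix,
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    alpha: float = 0.05,
    d_threshold: float = 0.15,
) -> pd.DataFrame:
    """Two-sample KS test per gene on log-normalized values.

    A gene is flagged ``shifted`` when p < ``alpha`` and D > ``d_threshold``.
    """
    mask_a = np.asarray(mask_a, dtype=bool)
    mask_b = np.asarray(mask_b, dtype=bool)
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise ValueError("each group needs at least 2 nuclei")
    a = nm.values[mask_a]
    b = nm.values[mask_b]
    d = np.empty(a.shape[1])
    p = np.empty(a.shape[1])
    for j in range(a.shape[1]):
        res = scipy.stats.ks_2samp(a[:, j], b[:, j], method="auto")
        d[j], p[j] = res.statistic, res.pvalue
    return pd.DataFrame(
        {"D": d, "p": p, "shifted": (p < alpha) & (d > d_threshold)},
        index=nm.gene_names,
    )


def ma_table(de: pd.DataFrame, mean_range: tuple[float, float] = (0.1, 100.0)) -> pd.DataFrame:
    """Restrict a DE table to the mean-expression window used for MA plots."""
    lo, hi = mean_range
    keep = (de["mean_norm"] >= lo) & (de["mean_norm"] <= hi)
    return de.loc[keep, ["mean_norm", "log2fc", "call"]].copy()


def de_summary(de: pd.DataFrame) -> dict:
    """Counts of up/down/ns calls for the JSON summary sidecar."""
    counts = de["call"].value_counts().to_dict()
    return {"up": int(counts.get("up", 0)), "down": int(counts.get("down", 0)), "ns": int(counts.get("ns", 0))}
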