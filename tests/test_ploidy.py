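"""Detection fold, Welch differential expression, and KS distribution shifts."""

import dataclasses
import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hepatoseq.ploidy import detected_genes_fold, ks_shift, ma_table, welch_de
from hepatoseq.normalization import log_transform, normalize_eq1
from hepatoseq.containers import SizeFactorTable

from conftest import make_count_matrix


def _nm_from_values(values, ploidy=None):
    """NormalizedMatrix in log space with the given values."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    cm = make_count_matrix(np.ones((n, m + 1), dtype=int), ercc_mask=[False] * m + [True],
                           ploidy=ploidy)
    sf = SizeFactorTable(pd.DataFrame({"sf": 1.0, "dilution_group": "1:100000"},
                                      index=cm.nuclei.index))
    nm = log_transform(normalize_eq1(cm, sf))
    return dataclasses.replace(nm, values=values)


# ---------------------------------------------------------------------------
# detection fold

def test_detection_fold_from_medians():
    counts = np.zeros((6, 1501), dtype=int)
    # 2n nuclei detect 1000/1200/1400 genes; 4n nuclei detect 1500 each
    for i, k in enumerate([1000, 1200, 1400, 1500, 1500, 1500]):
        counts[i, :k] = 1
    counts[:, -1] = 9  # spike-in column
    cm = make_count_matrix(counts, ercc_mask=[False] * 1500 + [True])
    a = np.array([1, 1, 1, 0, 0, 0], bool)
    assert detected_genes_fold(cm, a, ~a) == pytest.approx(1.25)
    assert detected_genes_fold(cm, a, a) == pytest.approx(1.0)


def test_detection_fold_degenerate_groups():
    cm = make_count_matrix(np.array([[0, 1], [1, 1]]), ercc_mask=[False, True])
    a = np.array([True, False])
    with pytest.raises(ValueError, match="zero"):
        detected_genes_fold(cm, a, ~a)
    with pytest.raises(ValueError, match="non-empty"):
        detected_genes_fold(cm, np.zeros(2, bool), a)


# ---------------------------------------------------------------------------
# Welch t

def _welch_by_hand(x, y):
    """Textbook Welch t and Welch-Satterthwaite df, scalar arithmetic."""
    n1, n2 = len(x), len(y)
    m1 = sum(x) / n1
    m2 = sum(y) / n2
    v1 = sum((xi - m1) ** 2 for xi in x) / (n1 - 1)
    v2 = sum((yi - m2) ** 2 for yi in y) / (n2 - 1)
    se2 = v1 / n1 + v2 / n2
    t = (m1 - m2) / math.sqrt(se2)
    df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return t, df


def test_welch_t_matches_textbook_formula():
    rng = np.random.default_rng(3)
    for _ in range(100):
        x = rng.normal(0, 1, rng.integers(3, 12)).tolist()
        y = rng.normal(0.5, 2, rng.integers(3, 12)).tolist()
        values = np.zeros((len(x) + len(y), 2))
        values[:, 0] = x + y
        values[:, 1] = 1.0  # constant companion gene
        nm = _nm_from_values(values)
        mask = np.array([True] * len(x) + [False] * len(y))
        de = welch_de(nm, mask, ~mask)
        t_ref, _ = _welch_by_hand(x, y)
        assert de["t_stat"].iloc[0] == pytest.approx(t_ref, abs=1e-10)
        assert de["p"].iloc[1] == 1.0  # zero-variance gene: no evidence


def test_welch_de_agrees_with_scanpy_rank_genes_groups():
    import anndata as ad
    import scanpy as sc

    rng = np.random.default_rng(4)
    values = np.log1p(rng.poisson(3, size=(80, 50)).astype(float))
    values[:40, :5] += 1.0
    nm = _nm_from_values(values)
    mask = np.array([True] * 40 + [False] * 40)
    de = welch_de(nm, mask, ~mask)

    adata = ad.AnnData(X=values.copy(),
                       obs=pd.DataFrame({"grp": ["a"] * 40 + ["b"] * 40}),
                       var=pd.DataFrame(index=nm.gene_names))
    adata.obs["grp"] = adata.obs["grp"].astype("category")
    sc.tl.rank_genes_groups(adata, "grp", groups=["a"], reference="b", method="t-test")
    order = list(adata.uns["rank_genes_groups"]["names"]["a"])
    sc_t = pd.Series(adata.uns["rank_genes_groups"]["scores"]["a"], index=order)
    sc_lfc = pd.Series(adata.uns["rank_genes_groups"]["logfoldchanges"]["a"], index=order)
    ours_t = de["t_stat"].loc[order]
    np.testing.assert_allclose(ours_t.to_numpy(), sc_t.to_numpy(), rtol=1e-4)
    np.testing.assert_allclose(de["log2fc"].loc[order].to_numpy(), sc_lfc.to_numpy(),
                               rtol=1e-3, atol=1e-3)


def test_identical_groups_yield_no_calls_and_antisymmetry():
    rng = np.random.default_rng(5)
    values = np.log1p(rng.poisson(4, size=(60, 30)).astype(float))
    nm = _nm_from_values(values)
    mask = np.array([True] * 30 + [False] * 30)
    # identical groups: duplicate rows
    same = _nm_from_values(np.vstack([values[:30], values[:30]]))
    de0 = welch_de(same, mask, ~mask)
    assert (de0["call"] != "ns").sum() == 0
    # swapping groups flips the fold change and the calls
    values[:30, :4] += 2.0
    nm = _nm_from_values(values)
    de_ab = welch_de(nm, mask, ~mask)
    de_ba = welch_de(nm, ~mask, mask)
    np.testing.assert_allclose(de_ab["log2fc"], -de_ba["log2fc"], atol=1e-9)
    assert ((de_ab["call"] == "up") == (de_ba["call"] == "down")).all()


def test_group_size_precondition():
    nm = _nm_from_values(np.ones((4, 3)))
    with pytest.raises(ValueError, match="at least 2"):
        welch_de(nm, np.array([1, 0, 0, 0], bool), np.array([0, 1, 1, 1], bool))


# ---------------------------------------------------------------------------
# KS shifts

def _ks_brute_force(a, b):
    """Sup distance of the two empirical CDFs over all pooled breakpoints."""
    points = sorted(set(list(a) + list(b)))
    d = 0.0
    for x in points:
        fa = sum(v <= x for v in a) / len(a)
        fb = sum(v <= x for v in b) / len(b)
        d = max(d, abs(fa - fb))
    return d


def test_ks_statistic_examples_and_brute_force():
    nm = _nm_from_values(np.array([[0.0], [0.2], [0.4], [0.6], [0.5], [0.7], [0.9], [1.1]]))
    mask = np.array([1, 1, 1, 1, 0, 0, 0, 0], bool)
    res = ks_shift(nm, mask, ~mask)
    assert res["D"].iloc[0] == pytest.approx(0.75)
    # identical samples
    same = _nm_from_values(np.array([[0.1], [0.5], [0.1], [0.5]]))
    res0 = ks_shift(same, np.array([1, 1, 0, 0], bool), np.array([0, 0, 1, 1], bool))
    assert res0["D"].iloc[0] == 0.0
    assert not res0["shifted"].iloc[0]
    # disjoint supports
    disj = _nm_from_values(np.array([[0.0], [0.1], [5.0], [6.0]]))
    assert ks_shift(disj, np.array([1, 1, 0, 0], bool),
                    np.array([0, 0, 1, 1], bool))["D"].iloc[0] == 1.0
    # randomized agreement with the brute-force sup
    rng = np.random.default_rng(6)
    for _ in range(100):
        na, nb = rng.integers(3, 15), rng.integers(3, 15)
        vals = np.round(rng.normal(0, 1, (na + nb, 1)), 1)  # ties likely
        nm = _nm_from_values(vals - vals.min())
        mask = np.zeros(na + nb, bool)
        mask[:na] = True
        d = ks_shift(nm, mask, ~mask)["D"].iloc[0]
        assert d == pytest.approx(_ks_brute_force(vals[:na, 0], vals[na:, 0]), abs=1e-12)


def test_ks_invariant_to_monotone_transform():
    rng = np.random.default_rng(7)
    vals = rng.gamma(2, 1, (40, 3))
    mask = np.zeros(40, bool)
    mask[:20] = True
    d1 = ks_shift(_nm_from_values(vals), mask, ~mask)["D"]
    d2 = ks_shift(_nm_from_values(np.sqrt(vals) + 2), mask, ~mask)["D"]
    np.testing.assert_allclose(d1, d2, atol=1e-12)


# ---------------------------------------------------------------------------
# MA table

def test_ma_table_window_matches_enumeration():
    rng = np.random.default_rng(8)
    values = np.log1p(rng.gamma(1, 3, size=(30, 40)))
    nm = _nm_from_values(values)
    mask = np.zeros(30, bool)
    mask[:15] = True
    de = welch_de(nm, mask, ~mask)
    table = ma_table(de, mean_range=(0.1, 100.0))
    expected = [(g, m) for g, m in de["mean_norm"].items() if 0.1 <= m <= 100.0]
    assert list(table.index) == [g for g, _ in expected]
    # explicit boundary cases
    fake = de.copy()
    fake.loc[fake.index[0], "mean_norm"] = 0.05   # below window
    fake.loc[fake.index[1], "mean_norm"] = 50.0   # inside window
    out = ma_table(fake)
    assert fake.index[0] not in out.index
    assert fake.index[1] in out.index
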