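"""ERCC size factors, the normalization identity, and downstream transforms."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from hepatoseq.normalization import (
    batch_correct,
    ercc_size_factors,
    log_transform,
    normalize_eq1,
    post_normalization_filter,
)
from hepatoseq.containers import SizeFactorTable

from conftest import make_count_matrix


def _unit_sf(cm):
    return SizeFactorTable(
        pd.DataFrame(
            {"sf": 1.0, "dilution_group": cm.nuclei["dilution_group"]}, index=cm.nuclei.index
        )
    )


# ---------------------------------------------------------------------------
# size factors

def test_size_factors_are_ercc_sums_over_group_mean():
    cm = make_count_matrix(
        np.array([[1, 100], [1, 300]]), ercc_mask=[False, True]
    )
    sf = ercc_size_factors(cm)
    np.testing.assert_allclose(sf.sf.to_numpy(), [0.5, 1.5])


def test_single_nucleus_group_gets_unit_factor():
    cm = make_count_matrix(np.array([[3, 42]]), ercc_mask=[False, True])
    assert ercc_size_factors(cm).sf.iloc[0] == pytest.approx(1.0)


def test_dilution_groups_are_independent():
    rng = np.random.default_rng(0)
    counts = rng.poisson(5, size=(12, 6)) + 1
    groups = ["1:100000"] * 7 + ["1:300000"] * 5
    cm = make_count_matrix(counts, ercc_mask=[False] * 4 + [True] * 2, dilution=groups)
    joint = ercc_size_factors(cm)
    # computing each group on its own split matrix must give identical factors
    for g in set(groups):
        mask = (cm.nuclei["dilution_group"] == g).to_numpy()
        split = ercc_size_factors(cm.subset(mask, None))
        np.testing.assert_allclose(
            joint.table.loc[split.table.index, "sf"], split.sf, rtol=1e-12
        )


def test_zero_ercc_nucleus_is_an_error_naming_it():
    cm = make_count_matrix(np.array([[5, 0], [5, 9]]), ercc_mask=[False, True])
    with pytest.raises(ValueError, match="N000"):
        ercc_size_factors(cm)


def test_group_means_equal_one(default_run):
    sf = default_run.normalized.size_factors
    means = sf.table.groupby("dilution_group", observed=True)["sf"].mean()
    np.testing.assert_allclose(means.to_numpy(), 1.0, rtol=1e-9)


# ---------------------------------------------------------------------------
# the normalization identity

def test_hand_evaluated_normalization():
    # counts (10, 30), lengths (1, 2) kb, sf = 1:
    # per-kb (10, 15), total 25, factor 25/10000 -> (4000, 6000)
    cm = make_count_matrix(
        np.array([[10, 30, 5]]), ercc_mask=[False, False, True], lengths=[1.0, 2.0, 1.0]
    )
    nm = normalize_eq1(cm, _unit_sf(cm))
    np.testing.assert_allclose(nm.values, [[4000.0, 6000.0]])


def test_per_nucleus_totals_equal_scale_times_sf():
    rng = np.random.default_rng(1)
    counts = rng.poisson(4, size=(20, 10)) + 1
    cm = make_count_matrix(
        counts,
        ercc_mask=[False] * 8 + [True] * 2,
        lengths=rng.uniform(0.3, 5.0, 10).tolist(),
    )
    sf = ercc_size_factors(cm)
    nm = normalize_eq1(cm, sf)
    np.testing.assert_allclose(
        nm.values.sum(axis=1), 10_000.0 * sf.sf.to_numpy(), rtol=1e-8
    )


def test_uniform_count_scaling_is_removed_when_sf_fixed():
    base = np.array([[4, 7, 1, 9]])
    cm1 = make_count_matrix(base, ercc_mask=[False, False, False, True])
    cm2 = make_count_matrix(base * 2, ercc_mask=[False, False, False, True])
    nm1 = normalize_eq1(cm1, _unit_sf(cm1))
    nm2 = normalize_eq1(cm2, _unit_sf(cm2))
    np.testing.assert_allclose(nm1.values, nm2.values, rtol=1e-12)


def test_zero_endogenous_nucleus_and_bad_length_are_errors():
    cm = make_count_matrix(np.array([[0, 0, 5]]), ercc_mask=[False, False, True])
    with pytest.raises(ValueError, match="zero endogenous"):
        normalize_eq1(cm, _unit_sf(cm))
    with pytest.raises(ValueError, match="length_kb"):
        make_count_matrix(np.array([[1, 2]]), lengths=[0.0, 1.0])


# ---------------------------------------------------------------------------
# post-normalization filter and log transform

def test_high_coverage_cells_removed_after_normalization():
    # by the identity, a cell's normalized total is 10000 * sf: sf = 6 -> 60000
    counts = np.array([[50, 600], [50, 40], [50, 80]])
    cm = make_count_matrix(counts, ercc_mask=[False, True])
    sf = ercc_size_factors(cm)
    assert sf.sf.max() == pytest.approx(600 / 240)  # not yet over threshold
    nm = normalize_eq1(cm, sf)
    assert post_normalization_filter(nm).n_nuclei == 3  # all sf <= 5: identity
    tight = post_normalization_filter(nm, max_total=20_000)
    assert tight.n_nuclei == 2  # the sf=2.5 cell (25000) is removed


def test_post_filter_refuses_log_values():
    cm = make_count_matrix(np.array([[5, 5]]), ercc_mask=[False, True])
    nm = log_transform(normalize_eq1(cm, _unit_sf(cm)))
    with pytest.raises(ValueError):
        post_normalization_filter(nm)


def test_log_transform_values_and_double_application():
    cm = make_count_matrix(np.array([[10, 30, 5]]), ercc_mask=[False, False, True],
                           lengths=[1.0, 2.0, 1.0])
    nm = normalize_eq1(cm, _unit_sf(cm))
    logged = log_transform(nm)
    np.testing.assert_allclose(logged.values, np.log1p(nm.values))
    assert logged.is_log
    # ordering preserved and zero maps to zero
    assert np.all(np.argsort(logged.values[0]) == np.argsort(nm.values[0]))
    with pytest.raises(ValueError, match="already log"):
        log_transform(logged)


# ---------------------------------------------------------------------------
# batch correction

def _log_nm(values, plates):
    n, m = values.shape
    cm = make_count_matrix(np.ones((n, m + 1), dtype=int),
                           ercc_mask=[False] * m + [True], plates=plates)
    nm = log_transform(normalize_eq1(cm, _unit_sf(cm)))
    return dataclasses.replace(nm, values=np.asarray(values, dtype=float))


def test_combat_is_nearly_identity_without_batch_effect():
    rng = np.random.default_rng(7)
    values = np.tile(rng.normal(2, 0.5, size=(30, 20)), (2, 1))
    corrected = batch_correct(_log_nm(values, ["P1"] * 30 + ["P2"] * 30))
    assert np.max(np.abs(corrected.values - values)) < 0.05


def test_combat_removes_planted_plate_offset():
    # noise small enough that a residual 5% of delta is resolvable:
    # per-gene mean-gap sampling noise is sigma * sqrt(2/n) ~ 0.014 << 0.1
    rng = np.random.default_rng(8)
    delta = 2.0
    values = rng.normal(3, 0.1, size=(200, 40))
    plates = ["P1"] * 100 + ["P2"] * 100
    values[100:] += delta
    nm = _log_nm(values, plates)
    corrected = batch_correct(nm)
    gap = corrected.values[100:].mean(axis=0) - corrected.values[:100].mean(axis=0)
    assert np.abs(gap).max() < 0.05 * delta
    # shape, order, and per-gene overall means preserved (to EB accuracy)
    assert corrected.values.shape == values.shape
    assert corrected.nuclei.index.equals(nm.nuclei.index)
    np.testing.assert_allclose(
        corrected.values.mean(axis=0), values.mean(axis=0), atol=0.01
    )


def test_combat_requires_log_and_two_nuclei_per_plate():
    cm = make_count_matrix(np.ones((4, 3), dtype=int), ercc_mask=[False, False, True],
                           plates=["P1", "P1", "P2", "P2"])
    nm = normalize_eq1(cm, _unit_sf(cm))
    with pytest.raises(ValueError, match="log"):
        batch_correct(nm)
    singleton = make_count_matrix(np.ones((3, 3), dtype=int), ercc_mask=[False, False, True],
                                  plates=["P1", "P1", "P2"])
    nm2 = log_transform(normalize_eq1(singleton, _unit_sf(singleton)))
    with pytest.raises(ValueError, match="fewer than 2"):
        batch_correct(nm2)
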