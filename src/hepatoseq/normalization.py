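"""ERCC spike-in size factors and gene-length/coverage normalization.

Size factors are the per-nucleus ERCC read totals divided by the mean ERCC
total across nuclei within the same dilution group, so they average to one
within each group.  Expression is then normalized per gene length and per
cell coverage:

    x'_ij = (x_ij / L_j) / ( sum_j (x_ij / L_j) / (C * sf_i) )

with L_j the gene length in kilobases, sf_i the ERCC size factor and C the
scale constant (default 10 000).  The identity sum_j x'_ij = C * sf_i holds
for every nucleus and is the central contract of the normalization: nuclei
whose ERCC content indicates high capture keep proportionally larger totals,
so genuine global differences in transcript content between ploidy classes
survive while technical coverage differences are removed.

After normalization, cells with more than 50 000 length-normalized total
counts are removed, values are log(1+x)-transformed, and plate batch effects
can optionally be corrected with ComBat.
"""

from __future__ import annotations

import dataclasses
import warnings

import anndata as ad
import numpy as np
import pandas as pd

from hepatoseq.containers import CountMatrix, NormalizedMatrix, SizeFactorTable


def ercc_size_factors(cm: CountMatrix) -> SizeFactorTable:
    """ERCC size factors per nucleus, computed within dilution groups.

    sf_i = (ERCC total of nucleus i) / mean(ERCC totals in i's dilution group)

    Raises if any nucleus has zero ERCC reads (such nuclei fail the QC ERCC
    fraction floor and should have been removed upstream).
    """
    ercc_sum = cm.ercc_counts.sum(axis=1).astype(float)
    if np.any(ercc_sum <= 0):
        bad = cm.nuclei.index[ercc_sum <= 0].tolist()[:5]
        raise ValueError(f"nuclei with zero ERCC reads (should have failed QC): {bad}")
    groups = cm.nuclei["dilution_group"]
    group_mean = pd.Series(ercc_sum, index=cm.nuclei.index).groupby(groups, observed=True).transform("mean")
    sf = ercc_sum / group_mean.to_numpy()
    return SizeFactorTable(
        pd.DataFrame({"sf": sf, "dilution_group": groups.to_numpy()}, index=cm.nuclei.index)
    )


def normalize_eq1(
    cm: CountMatrix, sf: SizeFactorTable, scale_constant: float = 10_000.0
) -> NormalizedMatrix:
    """Gene-length and ERCC-coverage normalization of the endogenous counts.

    ERCC features are excluded from the output.  Errors on nuclei with zero
    endogenous reads or genes with missing lengths.
    """
    endo = ~cm.is_ercc
    lengths = cm.features.loc[endo, "length_kb"].to_numpy(dtype=float)
    if np.any(~np.isfinite(lengths)) or np.any(lengths <= 0):
        raise ValueError("all endogenous genes need a positive length_kb")
    x = cm.counts[:, endo].astype(float)
    per_kb = x / lengths[None, :]
    totals = per_kb.sum(axis=1)
    if np.any(totals <= 0):
        bad = cm.nuclei.index[totals <= 0].tolist()[:5]
        raise ValueError(f"nuclei with zero endogenous counts: {bad}")
    sf_vec = sf.align(cm.nuclei.index)
    norm_factor = totals / (scale_constant * sf_vec)
    values = per_kb / norm_factor[:, None]
    return NormalizedMatrix(
        values=values,
        genes=cm.features.loc[endo].copy(),
        nuclei=cm.nuclei.copy(),
        size_factors=sf,
        scale_constant=scale_constant,
        is_log=False,
    )


def post_normalization_filter(nm: NormalizedMatrix, max_total: float = 50_000.0) -> NormalizedMatrix:
    """Remove cells with more than ``max_total`` length-normalized total counts."""
    if nm.is_log:
        raise ValueError("post-normalization filter must run before the log transform")
    totals = nm.values.sum(axis=1)
    keep = totals <= max_total
    return nm.subset_nuclei(keep)


def log_transform(nm: NormalizedMatrix) -> NormalizedMatrix:
    """Natural log of one plus the normalized values."""
    if nm.is_log:
        raise ValueError("matrix is already log-transformed")
    return dataclasses.replace(nm, values=np.log1p(nm.values), is_log=True)


def batch_correct(nm: NormalizedMatrix, covariate: str = "plate_id") -> NormalizedMatrix:
    """ComBat empirical-Bayes location/scale batch correction across plates.

    Requires log-transformed input and at least two nuclei per batch level.
    With a single batch level the input is returned unchanged.
    """
    if not nm.is_log:
        raise ValueError("batch correction expects log-transformed values")
    batches = nm.nuclei[covariate].astype(str)
    sizes = batches.value_counts()
    if len(sizes) < 2:
        return nm.copy()
    if (sizes < 2).any():
        raise ValueError(f"batches with fewer than 2 nuclei: {sizes[sizes < 2].index.tolist()}")
    # zero-variance genes carry no batch signal and would divide by zero
    varying = nm.values.var(axis=0) > 0
    corrected = nm.values.copy()
    if varying.any():
        adata = ad.AnnData(
            X=nm.values[:, varying].copy(),
            obs=pd.DataFrame({"batch": batches.to_numpy()}, index=nm.nuclei.index),
        )
        import scanpy as sc

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sc.pp.combat(adata, key="batch")
        corrected[:, varying] = np.asarray(adata.X, dtype=float)
    return dataclasses.replace(nm, values=corrected, is_batch_corrected=True)
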