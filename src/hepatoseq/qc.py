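"""Per-nucleus QC metrics and the ordered filter cascade.

The cascade applies four steps in a fixed order:

1. keep nuclei whose ERCC read fraction lies strictly between 5% and 90%;
2. keep nuclei with strictly more than 1000 and fewer than 7000 endogenous
   genes detected;
3. keep endogenous genes detected in at least 25 of the remaining nuclei and
   with at least 250 total reads (ERCC features are never removed here);
4. keep nuclei with fewer than 7000 genes detected and a library size between
   10 000 and 300 000 reads (inclusive).

Nucleus-level metrics (genes detected, library size, ERCC fraction) are
computed once on the input matrix and reused by every nucleus step, i.e. the
gene filter does not retroactively change a nucleus's detection count.
Library size counts all mapped reads including ERCC by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from hepatoseq.containers import CountMatrix, FilterReport


@dataclass(frozen=True)
class QCThresholds:
    """Filter cascade thresholds (defaults are the study's values).

    ``gene_filter_mode`` controls how the two gene criteria combine:
    ``"and"`` keeps genes meeting both (detected in >= ``gene_min_nuclei``
    nuclei AND >= ``gene_min_reads`` total reads); ``"or"`` keeps genes
    meeting either one.
    """

    ercc_frac_min: float = 0.05   # strict lower bound
    ercc_frac_max: float = 0.90   # strict upper bound
    n_genes_min: int = 1000       # strict
    n_genes_max: int = 7000       # strict
    gene_min_nuclei: int = 25
    gene_min_reads: int = 250
    gene_filter_mode: str = "and"
    library_min: int = 10_000     # inclusive
    library_max: int = 300_000    # inclusive
    library_includes_ercc: bool = True

    def __post_init__(self) -> None:
        if self.ercc_frac_min < 0 or self.ercc_frac_max > 1 or self.ercc_frac_min >= self.ercc_frac_max:
            raise ValueError("invalid ERCC fraction window")
        if self.n_genes_min < 0 or self.n_genes_min >= self.n_genes_max:
            raise ValueError("invalid genes-detected window")
        if self.library_min < 0 or self.library_min > self.library_max:
            raise ValueError("invalid library size window")
        if self.gene_filter_mode not in ("and", "or"):
            raise ValueError("gene_filter_mode must be 'and' or 'or'")


def compute_qc(cm: CountMatrix, library_includes_ercc: bool = True) -> pd.DataFrame:
    """Per-nucleus QC metrics.

    Returns a DataFrame indexed by nucleus_id with columns

    - ``library_size``: total read count (all features, or endogenous only if
      ``library_includes_ercc`` is False);
    - ``n_genes_detected``: endogenous genes with count > 0;
    - ``ercc_fraction``: ERCC reads / total reads (0 for an empty nucleus).
    """
    total = cm.counts.sum(axis=1)
    ercc_total = cm.ercc_counts.sum(axis=1)
    library = total if library_includes_ercc else total - ercc_total
    n_genes = (cm.endogenous_counts > 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ercc_fraction = np.where(total > 0, ercc_total / np.maximum(total, 1), 0.0)
    return pd.DataFrame(
        {
            "library_size": library.astype(np.int64),
            "n_genes_detected": n_genes.astype(np.int64),
            "ercc_fraction": ercc_fraction,
        },
        index=cm.nuclei.index,
    )


def apply_qc_filters(
    cm: CountMatrix, thresholds: QCThresholds | None = None
) -> tuple[CountMatrix, FilterReport]:
    """Apply the four-step filter cascade; returns the kept matrix and report."""
    thr = thresholds or QCThresholds()
    report = FilterReport(thresholds=asdict(thr))
    report.add("input", cm.n_nuclei, cm.n_features)

    metrics = compute_qc(cm, library_includes_ercc=thr.library_includes_ercc)
    ef = metrics["ercc_fraction"].to_numpy()
    ng = metrics["n_genes_detected"].to_numpy()
    lib = metrics["library_size"].to_numpy()

    # step 1: ERCC fraction window (strict)
    keep_nuc = (ef > thr.ercc_frac_min) & (ef < thr.ercc_frac_max)
    report.add("ercc_fraction_window", keep_nuc.sum(), cm.n_features)

    # step 2: genes-detected window (strict)
    keep_nuc &= (ng > thr.n_genes_min) & (ng < thr.n_genes_max)
    report.add("genes_detected_window", keep_nuc.sum(), cm.n_features)

    # step 3: gene filter, evaluated over the surviving nuclei
    endo = ~cm.is_ercc
    sub = cm.counts[keep_nuc]
    det_in = (sub > 0).sum(axis=0)
    reads = sub.sum(axis=0)
    ok_det = det_in >= thr.gene_min_nuclei
    ok_reads = reads >= thr.gene_min_reads
    gene_ok = (ok_det & ok_reads) if thr.gene_filter_mode == "and" else (ok_det | ok_reads)
    keep_feat = ~endo | gene_ok  # ERCC features always kept
    report.add("gene_filter", keep_nuc.sum(), keep_feat.sum())

    # step 4: genes-detected ceiling and library window (pre-gene-filter metrics)
    keep_nuc &= (ng < thr.n_genes_max) & (lib >= thr.library_min) & (lib <= thr.library_max)
    report.add("library_and_gene_ceiling", keep_nuc.sum(), keep_feat.sum())

    out = cm.subset(keep_nuc, keep_feat)
    if out.n_nuclei == 0 or (~out.is_ercc).sum() == 0:
        warnings.warn("QC cascade left an empty matrix", stacklevel=2)
    return out, report


def drop_technical_replicates(cm: CountMatrix) -> CountMatrix:
    """Remove nuclei flagged as technical replicates."""
    flagged = cm.nuclei["is_technical_replicate"].to_numpy(dtype=bool)
    if flagged.all() and len(flagged):
        warnings.warn("all nuclei are flagged as technical replicates", stacklevel=2)
    return cm.subset(~flagged, None)
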