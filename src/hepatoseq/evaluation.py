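"""Recovery metrics: pipeline output vs the generator's planted truth.

Used by the test suite and the acceptance script to score how well each
analysis stage recovers what the generator planted.  The differential
expression score is computed on the zonation-unconfounded gene universe:
genes planted with an expression gradient along the lobule are genuinely
shifted between ploidy classes through the biased 4n placement (the
zonation-ploidy crosstalk the pipeline is designed to expose), so they are
neither true nor false positives of the planted-DEG contrast and are
excluded from both the call set and the truth set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.stats

from hepatoseq.pipeline import PipelineResult
from hepatoseq.simulate import STEM_MODULE, GroundTruth


def deg_precision_recall(res: PipelineResult) -> tuple[float, float]:
    """Precision and recall of DE calls against the planted DEG set.

    Evaluated over genes with no planted zonation gradient (see module
    docstring); the stem markers are likewise excluded because their planted
    structure is binary co-detection, not a mean shift.
    """
    truth: GroundTruth = res.truth
    g = truth.genes
    universe = set(g.index[(g["zonation_class"] == "none") & ~g["stem_marker"]])
    de = res.de_2n_4n
    called = {x for x in de.index[de["call"] != "ns"] if x in universe}
    true_set = set(g.index[g["deg"] != "none"]) & universe
    tp = len(called & true_set)
    precision = tp / len(called) if called else 1.0
    recall = tp / len(true_set) if true_set else 1.0
    return precision, recall


def detection_fold_error(res: PipelineResult) -> float:
    """Measured minus planted detected-gene fold (4n over 2n hepatocytes)."""
    return float(res.detected_fold - res.truth.detection_fold)


def enrichment_error(res: PipelineResult) -> float:
    """Measured minus planted pericentral 4n enrichment."""
    return float(res.enrichment - res.truth.planted_enrichment)


def module_recovered(res: PipelineResult) -> bool:
    """True when the planted stem module is extracted exactly (as one module)."""
    return sorted(STEM_MODULE) in [sorted(m) for m in (res.modules or [])]


def dpt_spearman(res: PipelineResult) -> float:
    """|Spearman rho| between pseudospace and the latent lobule coordinate.

    Restricted to nuclei that truly are hepatocytes (an occasional stray
    nucleus of another type in the hepatocyte cluster has no lobule
    coordinate).
    """
    z = res.truth.nuclei.loc[res.hepatocytes.nuclei.index, "z"]
    ok = (~z.isna()).to_numpy()
    rho = scipy.stats.spearmanr(res.zonation.dpt.to_numpy()[ok], z.to_numpy()[ok]).statistic
    return float(abs(rho))


def recovery_report(res: PipelineResult) -> dict:
    """All planted-recovery metrics for one pipeline run."""
    precision, recall = deg_precision_recall(res)
    return {
        "deg_precision": precision,
        "deg_recall": recall,
        "detection_fold": float(res.detected_fold),
        "detection_fold_error": detection_fold_error(res),
        "enrichment": float(res.enrichment),
        "enrichment_error": enrichment_error(res),
        "module_recovered": bool(module_recovered(res)),
        "dpt_spearman_abs": dpt_spearman(res),
        "cv_ratio_2n_over_4n": float(res.variability.ratio_of_medians),
    }
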