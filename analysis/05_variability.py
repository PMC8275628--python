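"""Transcriptional variability of 2n vs 4n hepatocytes.

Per-gene coefficients of variation on log expression, the ratio of group
medians with a Mann-Whitney U test, and counts of highly variable genes that
are not differentially expressed.
"""

import json

from pipeline_state import RESULTS, stages_up_to


def main() -> None:
    cfg, res = stages_up_to("variability")
    v = res.variability
    out = {
        "cv_ratio_2n_over_4n": v.ratio_of_medians,
        "mann_whitney_p": v.mw_p,
        "n_genes_compared": int(len(v.cv_a)),
        "hvg_2n": res.hvg_2n.n_hvg,
        "hvg_2n_non_de": res.hvg_2n.n_hvg_non_de,
        "hvg_4n": res.hvg_4n.n_hvg,
        "hvg_4n_non_de": res.hvg_4n.n_hvg_non_de,
    }
    (RESULTS / "variability_summary.json").write_text(json.dumps(out, indent=2))
    v.cv_a.to_frame("cv_2n").join(v.cv_b.rename("cv_4n")).to_csv(
        RESULTS / "gene_cv.tsv", sep="\t"
    )

    print(f"2n hepatocytes are {v.ratio_of_medians:.2f}x more variable than 4n "
          f"(Mann-Whitney p = {v.mw_p:.2e}, {out['n_genes_compared']} genes)")
    print(f"non-DE HVGs: {out['hvg_2n_non_de']} in 2n vs {out['hvg_4n_non_de']} in 4n")


if __name__ == "__main__":
    main()
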