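"""Binary co-expression of stem/progenitor markers in hepatocytes.

Binarizes log expression, restricts to the stem panel, computes pairwise
Jaccard distances between markers, extracts modules by cutting the
average-linkage tree, and counts nuclei co-expressing two or more markers
per ploidy class.
"""

import json

from pipeline_state import RESULTS, stages_up_to


def main() -> None:
    cfg, res = stages_up_to("coexpr")
    res.jaccard.distance.round(4).to_csv(RESULTS / "jaccard_distance.tsv", sep="\t")
    (RESULTS / "stem_modules.json").write_text(json.dumps(res.modules, indent=2))
    res.coexpr_summary.to_csv(RESULTS / "coexpression_counts.tsv", sep="\t")

    print("stem-marker co-expression modules (tree cut at distance 0.5):")
    for mod in res.modules:
        print("  " + ", ".join(mod))
    print("\nfraction of nuclei co-expressing >= 2 stem markers per ploidy:")
    print(res.coexpr_summary.round(3).to_string())


if __name__ == "__main__":
    main()
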