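"""Graph clustering and marker-panel annotation of liver cell types.

PCA + kNN + Leiden on the log-normalized matrix, then each cluster is
labeled by its maximal z-scored marker-panel score; the hepatocyte cluster
is extracted for all downstream ploidy and zonation analyses.
"""

import pandas as pd

from pipeline_state import RESULTS, stages_up_to


def main() -> None:
    cfg, res = stages_up_to("cluster")
    res.clusters.table.to_csv(RESULTS / "clusters.tsv", sep="\t")

    counts = res.clusters.table.groupby(["cluster", "cell_type"]).size()
    print("cluster -> cell type assignment:")
    print(counts.to_string())
    labels = res.clusters.cell_type.value_counts()
    print("\ncell-type composition:")
    print((labels / labels.sum()).round(3).to_string())
    hep = res.hepatocytes
    pl = hep.nuclei["ploidy"].value_counts()
    print(f"\nhepatocyte compartment: {hep.n_nuclei} nuclei "
          f"({pl.get('2n', 0)} x 2n, {pl.get('4n', 0)} x 4n)")


if __name__ == "__main__":
    main()
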