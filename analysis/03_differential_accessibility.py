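"""Differential accessibility over 500 bp summit windows.

Builds the normalized count matrix on summit windows of the top pooled
peaks, applies the >5-fold / p<0.05 screen, and orders samples by
1-Pearson hierarchical clustering and PCA.
"""

import pandas as pd

from common import default_dataset, results_path
from atacdiff.peaks_accessibility import (
    cluster_samples,
    count_matrix,
    differential_accessibility,
    differential_regions_to_frame,
    pca_samples,
    pool_and_recall,
    summit_windows,
    top_regions,
    write_differential_bed,
)


def main():
    config, genome, truth, tracks, groups, *_ = default_dataset()
    sizes = config.chrom_lengths()
    peaks = pool_and_recall(tracks, sizes)
    windows, _ = summit_windows(top_regions(peaks, 50_000), sizes, width=500)
    matrix = count_matrix(windows, tracks)
    matrix.to_frame().reset_index(names="region").to_csv(
        results_path("03_norm_counts.tsv"), sep="\t", index=False,
        float_format="%.6g",
    )

    diffs = differential_accessibility(matrix, groups, fold_cut=5.0, p_cut=0.05)
    write_differential_bed(diffs, results_path("03_differential_regions.bed"))
    frame = differential_regions_to_frame(diffs)
    by_dir = frame["direction"].value_counts()
    print(f"{len(diffs)} differential regions of {len(windows)} windows "
          f"({by_dir.to_dict()})")

    clust = cluster_samples(matrix)
    order = [clust.labels[i] for i in clust.order]
    print(f"sample dendrogram leaf order: {order}")

    pca = pca_samples(matrix, k=2)
    coords = pd.DataFrame(pca.coordinates, index=pca.samples,
                          columns=["PC1", "PC2"])
    coords["group"] = [groups[s] for s in pca.samples]
    coords.to_csv(results_path("03_pca_coordinates.tsv"), sep="\t",
                  index_label="sample", float_format="%.6g")
    print(f"PC1/PC2 variance fractions: "
          f"{[round(float(v), 3) for v in pca.variance_fractions]}")
    print("-> results/03_differential_regions.bed, 03_norm_counts.tsv, "
          "03_pca_coordinates.tsv")


if __name__ == "__main__":
    main()
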