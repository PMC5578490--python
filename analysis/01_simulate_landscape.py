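"""Generate the default synthetic study and summarize what was planted.

Writes the ground-truth ledger and a per-class summary of planted regions,
motif instances and expression effects to results/.
"""

import pandas as pd

from common import default_dataset, results_path
from atacdiff.synthetic_data import save_truth


def main():
    config, genome, truth, tracks, groups, fpkm, perturb = default_dataset()
    save_truth(truth, results_path("01_truth.json"))

    peaks = pd.DataFrame(
        {
            "class": [p.peak_class for p in truth.planted_peaks],
            "rate_cancer": [p.rate_cancer for p in truth.planted_peaks],
            "rate_normal": [p.rate_normal for p in truth.planted_peaks],
        }
    )
    summary = peaks.groupby("class").agg(
        n=("class", "size"),
        rate_cancer=("rate_cancer", "mean"),
        rate_normal=("rate_normal", "mean"),
    )
    summary.to_csv(results_path("01_planted_peaks_summary.tsv"), sep="\t")

    motifs = pd.DataFrame(
        {
            "motif": [m.motif_id for m in truth.planted_motifs],
            "occupied": [m.occupied for m in truth.planted_motifs],
        }
    )
    motif_summary = motifs.value_counts().rename("n").reset_index()
    motif_summary.to_csv(results_path("01_planted_motifs_summary.tsv"),
                         sep="\t", index=False)

    print(f"genome: {sum(config.chrom_lengths().values()):,} bp "
          f"over {config.n_chroms} chromosomes, GC {config.gc_content}")
    print(summary)
    print(motif_summary)
    print(f"samples: {[t.sample_id for t in tracks]}, "
          f"libraries {[t.library_size for t in tracks]}")
    print(f"AP1-driven genes planted: {len(truth.ap1_driven_genes())}")
    print("truth ledger -> results/01_truth.json")


if __name__ == "__main__":
    main()
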