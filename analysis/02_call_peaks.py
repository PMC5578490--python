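"""Call peaks on the pooled cleavage track (merge-and-recall strategy).

Pools all five samples, calls peaks with the local-lambda Poisson scan and
checks how many planted regions the caller found.
"""

from common import default_dataset, results_path
from atacdiff.genomics_io import write_narrowpeak
from atacdiff.peaks_accessibility import pool_and_recall


def main():
    config, genome, truth, tracks, groups, *_ = default_dataset()
    sizes = config.chrom_lengths()
    peaks = pool_and_recall(tracks, sizes)
    write_narrowpeak(peaks, results_path("02_pooled_peaks.narrowPeak"))

    found = sum(
        any(pk.interval.overlaps(p.interval) for pk in peaks)
        for p in truth.planted_peaks
    )
    print(f"called {len(peaks)} peaks from "
          f"{sum(t.library_size for t in tracks):,} pooled events")
    print(f"planted regions overlapped by a called peak: "
          f"{found}/{len(truth.planted_peaks)}")
    print("-> results/02_pooled_peaks.narrowPeak")


if __name__ == "__main__":
    main()
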