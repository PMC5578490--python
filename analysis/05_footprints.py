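"""Tn5 cleavage footprints at AP1 motifs, occupied vs unoccupied.

Aggregates normalized cleavage +/-75 bp around planted AP1 instances in one
cancer and one normal sample and reports the scalar footprint depth.
"""

import pandas as pd

from common import default_dataset, results_path
from atacdiff.footprinting import cleavage_profile, footprint_depth


def main():
    config, genome, truth, tracks, groups, *_ = default_dataset()
    cancer = next(t for t in tracks if groups[t.sample_id] == "cancer")
    normal = next(t for t in tracks if groups[t.sample_id] == "normal")

    frames = []
    for occupied, label in ((True, "occupied"), (False, "unoccupied")):
        anchors = truth.motif_anchors("AP1", occupied=occupied)
        for track, cond in ((cancer, "cancer"), (normal, "normal")):
            profile = cleavage_profile(track, anchors, flank=75,
                                       description=f"AP1 {label} / {cond}")
            depth = footprint_depth(profile, core_halfwidth=3,
                                    flank_band=(25, 70))
            print(f"AP1 {label:10s} in {cond:6s} sample: "
                  f"depth={depth:+.3f} over {profile.n_anchors} anchors")
            frame = profile.to_frame()
            frame["anchors"] = label
            frame["condition"] = cond
            frames.append(frame)
    pd.concat(frames).to_csv(results_path("05_footprint_profiles.tsv"),
                             sep="\t", index=False, float_format="%.6g")
    print("-> results/05_footprint_profiles.tsv")


if __name__ == "__main__":
    main()
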