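"""Pixel-wise statistical gaze mapping over the age-group factor.

Builds z-scored gaze maps per trial, fits the per-pixel F map for the main
effect of age group (with pedestrian presence as a second fixed effect),
applies the bootstrap cluster-mass correction, reports significant areas in
full-resolution pixel units, and writes pairwise group contrasts.
"""

from pathlib import Path

import pandas as pd

from gazecross.gazemaps import build_gaze_map
from gazecross.geometry import DEFAULT_GEOMETRY
from gazecross.simulate import simulate_cohort
from gazecross.statmap import cluster_bootstrap_correct, contrast_map, pixelwise_fit, significant_area

from cohort_config import COHORT, SEED

OUT = Path(__file__).resolve().parents[1] / "results"
DOWNSAMPLE = 8  # 240 x 135 grid keeps the bootstrap brisk


def main() -> None:
    cohort = simulate_cohort(COHORT, seed=SEED)
    maps, rows = [], []
    for r in cohort.design.itertuples(index=False):
        rec = cohort.recordings[(r.participant_id, r.trial_id)]
        maps.append(build_gaze_map(rec, DEFAULT_GEOMETRY, downsample=DOWNSAMPLE))
        rows.append({
            "participant_id": r.participant_id,
            "age_group": r.age_group,
            "pedestrian_present": r.pedestrian_present,
        })
    design = pd.DataFrame(rows)

    un = pixelwise_fit(maps, design, "age_group", factors=["age_group", "pedestrian_present"])
    co = cluster_bootstrap_correct(un, maps, design, alpha=0.05, n_boot=300, seed=SEED,
                                   factors=["age_group", "pedestrian_present"])
    print(f"main effect of age group: F({co.df[0]:.0f}, {co.df[1]:.0f}), "
          f"cluster-forming threshold {co.threshold:.2f}")
    print(f"significant area {significant_area(co)} px (full 1920x1080 units), "
          f"{sum(c.significant for c in co.clusters)} of {len(co.clusters)} clusters retained")

    cluster_rows = [
        {"effect": "age_group", "label": c.label, "size_px": c.size_px,
         "mass": round(c.mass, 2), "significant": int(c.significant)}
        for c in co.clusters
    ]

    names = [g.name for g in COHORT.groups]
    for a, b in [(names[2], names[0]), (names[2], names[1]), (names[1], names[0])]:
        cm = contrast_map(maps, design, a, b, n_boot=300, seed=SEED)
        area = significant_area(cm)
        print(f"contrast {a} - {b}: significant area {area} px")
        cluster_rows += [
            {"effect": f"{a}-{b}", "label": c.label, "size_px": c.size_px,
             "mass": round(c.mass, 2), "significant": int(c.significant)}
            for c in cm.clusters
        ]
    pd.DataFrame(cluster_rows).to_csv(OUT / "statmap_clusters.tsv", sep="\t", index=False)
    print(f"wrote statmap_clusters.tsv to {OUT}")


if __name__ == "__main__":
    main()
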