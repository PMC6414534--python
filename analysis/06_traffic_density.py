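"""Estimate per-trial traffic density from rendered toy videos.

Renders one toy clip per vehicle-count level (moving rectangles along the
road line, optional pedestrian blob), runs Gaussian-mixture background
subtraction + blob counting, and compares estimated to true counts.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gazecross.simulate import render_traffic_video
from gazecross.traffic import count_vehicles

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 20260928


def main() -> None:
    rows = []
    for n in range(0, 6):
        for rep in range(3):
            seed = SEED + 13 * n + rep
            frames, truth = render_traffic_video(n, pedestrian_present=bool(rep % 2), seed=seed)
            est, _ = count_vehicles(frames)
            rows.append({"true_n": n, "pedestrian": int(rep % 2), "estimated_n": est,
                         "correct": int(est == n)})
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "traffic_density_estimates.csv", index=False)
    acc = df["correct"].mean()
    print(df.groupby("true_n")[["estimated_n", "correct"]].mean().round(2).to_string())
    print(f"overall exact-count accuracy: {acc:.0%} over {len(df)} rendered clips "
          f"(pedestrian blobs excluded by the blob-area threshold)")
    print(f"wrote traffic_density_estimates.csv to {OUT}")


if __name__ == "__main__":
    main()
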