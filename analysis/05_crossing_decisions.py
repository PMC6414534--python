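"""Road-crossing decision analysis: clustering, robust tests, density split.

Clusters participants by their mean number of crossing decisions per trial
(k-means++, k=2, 1000 restarts), compares press counts and durations
between the clusters with Yuen's 20%-trimmed-mean test, characterises
distributional differences with a decile shift function, and dichotomises
trials into low/high traffic density.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gazecross import io
from gazecross.decisions import density_split, kmeans_pp, shift_function, yuen_test

from cohort_config import SEED

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    decisions = io.read_decisions_csv(OUT / "decisions.csv")
    metadata = io.read_metadata_csv(OUT / "trial_metadata.csv")
    design = pd.read_csv(OUT / "design.csv", dtype={"participant_id": str, "trial_id": str})

    # participants' mean presses per trial; clustering restricted to children
    per_part = (
        pd.DataFrame([{"participant_id": d.participant_id, "n": d.n_presses} for d in decisions])
        .groupby("participant_id")["n"].mean()
    )
    group_of = design.drop_duplicates("participant_id").set_index("participant_id")["age_group"]
    children = per_part[group_of.loc[per_part.index].str.startswith("child")]
    res = kmeans_pp(children.to_numpy(), k=2, n_restarts=1000, seed=SEED)
    print(f"k-means on {len(children)} child participants: centroids "
          f"{res.centroids[0]:.2f} / {res.centroids[1]:.2f} (WCSS {res.wcss:.2f})")

    lower = children[res.assignments == 0]
    upper = children[res.assignments == 1]
    presses_by = {
        name: np.array([d.n_presses for d in decisions if d.participant_id in idx])
        for name, idx in (("lower", set(lower.index)), ("upper", set(upper.index)))
    }
    yt = yuen_test(presses_by["upper"], presses_by["lower"], trim=0.2)
    print(f"Yuen (press counts, upper vs lower cluster): t={yt.t:.2f}, df={yt.df:.1f}, "
          f"p={yt.p:.3g}, d={yt.d:.2f}")

    durs = {
        name: np.array([v for d in decisions if d.participant_id in idx for v in d.press_durations_ms])
        for name, idx in (("lower", set(lower.index)), ("upper", set(upper.index)))
    }
    yd = yuen_test(durs["upper"], durs["lower"], trim=0.2)
    print(f"Yuen (press durations): t={yd.t:.2f}, df={yd.df:.1f}, p={yd.p:.3g}, d={yd.d:.2f}")

    sf = shift_function(presses_by["upper"], presses_by["lower"], n_boot=1000, seed=SEED)
    pd.DataFrame({
        "decile": sf.deciles, "upper": sf.x_deciles, "lower": sf.y_deciles,
        "difference": sf.difference, "ci_low": sf.ci_low, "ci_high": sf.ci_high,
    }).to_csv(OUT / "shift_function_presses.tsv", sep="\t", index=False)
    print("shift function (upper - lower presses) decile differences: "
          + ", ".join(f"{d:.2f}" for d in sf.difference))

    counts = np.array([m.n_vehicles for m in metadata])
    classes, thr = density_split(counts, "kde")
    print(f"traffic density split: KDE centre {thr:.2f} -> "
          f"{np.mean(classes == 'high'):.0%} of trials high density")
    pd.DataFrame({
        "trial_id": [m.trial_id for m in metadata],
        "n_vehicles": counts,
        "density_class": classes,
    }).to_csv(OUT / "density_classes.csv", index=False)
    print(f"wrote shift_function_presses.tsv, density_classes.csv to {OUT}")


if __name__ == "__main__":
    main()
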