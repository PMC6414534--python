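"""Parse every trial into fixations, saccades and pursuits; apply QC.

Writes the per-trial event summary table and a per-group summary of counts
and proportions of trial time per event type, plus the QC report (removed
trials / excluded participants under the majority-supra-threshold rule).
"""

from pathlib import Path

import numpy as np
import pandas as pd

from gazecross.events import ParserParams, parse_trial, qc_filter, summarize_events
from gazecross.geometry import DEFAULT_GEOMETRY
from gazecross.simulate import simulate_cohort

from cohort_config import COHORT, SEED

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cohort = simulate_cohort(COHORT, seed=SEED)
    params = ParserParams()
    by_participant: dict[str, list] = {}
    for (pid, _), rec in cohort.recordings.items():
        by_participant.setdefault(pid, []).append(rec)

    kept, removed, excluded = qc_filter(by_participant, DEFAULT_GEOMETRY, params)
    print(f"QC: {len(removed)} trials removed, {len(excluded)} participants excluded")

    rows = []
    for pid, recs in kept.items():
        group = pid.rsplit("_p", 1)[0]
        for rec in recs:
            segs = parse_trial(rec, DEFAULT_GEOMETRY, params)
            s = summarize_events(segs, rec.duration_ms)
            row = {"participant_id": pid, "trial_id": rec.trial_id, "age_group": group}
            for lab in ("fixation", "saccade", "pursuit"):
                row[f"n_{lab}"] = s.counts[lab]
                row[f"ms_{lab}"] = s.total_ms[lab]
                row[f"prop_{lab}"] = s.proportions[lab]
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(OUT / "event_summaries.csv", index=False)

    group_tbl = df.groupby("age_group")[
        [c for c in df.columns if c.startswith(("n_", "prop_"))]
    ].mean().round(3)
    group_tbl.to_csv(OUT / "event_summary_by_group.csv")
    print("mean per-trial oculomotor characteristics by group:")
    print(group_tbl.to_string())
    total_prop = df[[f"prop_{l}" for l in ("fixation", "saccade", "pursuit")]].sum(axis=1)
    print(f"label proportions sum to {total_prop.min():.4f}..{total_prop.max():.4f} "
          f"(remainder is missing/blink time)")


if __name__ == "__main__":
    main()
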