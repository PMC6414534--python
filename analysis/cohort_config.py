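"""Shared study configuration for the analysis drivers.

A scaled-down cohort (5 participants per age group, 30 trials of 10 s at
1000 Hz) keeps every driver re-runnable in minutes while preserving the
design shape: three age groups with increasingly tight gaze bias toward the
vehicle appearing point, pedestrian presence on half the trials, and two
traffic regimes.  Drivers regenerate gaze from the seed instead of reading
multi-gigabyte sample files.
"""

import dataclasses

from gazecross.simulate import DEFAULT_COHORT

SEED = 20260928
N_PARTICIPANTS = 5
N_TRIALS = 30

COHORT = dataclasses.replace(
    DEFAULT_COHORT,
    groups=[dataclasses.replace(g, n_participants=N_PARTICIPANTS) for g in DEFAULT_COHORT.groups],
    n_trials=N_TRIALS,
)
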