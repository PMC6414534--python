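# gazecross

Analysis pipeline for gaze behaviour and crossing decisions while watching
road-traffic videos: oculomotor event parsing at 1000 Hz, gaze-similarity
mapping, pixel-wise statistical gaze maps, robust decision statistics, and
vehicle counting from video — driven end to end by a synthetic-data
generator with known ground truth.

It is written for eye-movement researchers who want to re-run this style of
road-crossing analysis on their own recordings (or on simulated cohorts) and
for anyone who needs the individual pieces: a smooth-pursuit-aware event
parser, gaze similarity matrices, or a cluster-corrected pixel-wise mapping
of gaze densities.

## What it computes

**Event parsing.** Gaze samples (x, y in screen pixels at 1000 Hz) are
converted to angular velocity using the monitor geometry (1920 × 1080 px,
521 × 293 mm at 600 mm viewing distance subtends 46.9° × 27.4°). Samples
faster than 50 deg/s are saccades. Runs holding ≤ 30 deg/s for ≥ 100 ms are
smooth-segment candidates; each is scored by fitting quadratics x(t), y(t)
and computing

```
score = P_RMSE / exp(A)
```

where `P_RMSE` is the root-mean-square residual of the fit and `A` the arc
length of the fitted 2-D curve (both in pixels). Scores below 1 × 10⁻⁹ are
smooth pursuit; everything else is fixation. A genuinely moving eye accrues
tens to hundreds of pixels of arc, so exp(A) explodes and the score
collapses; a jittering fixation keeps A at a few pixels and scores many
orders of magnitude higher. Quality control removes a trial when the
majority of its samples exceed the saccade threshold and excludes a
participant when more than half of their trials are removed.

**Gaze similarity.** Per trial, gaze positions are accumulated on the screen
grid, smoothed with a 1°-SD Gaussian and z-scored. The gaze similarity
matrix (GSM) holds Fisher-transformed Pearson correlations z = atanh(r)
between all trial pairs; averaging each trial's row and sorting gives a
consistency curve with participant-level bootstrap confidence intervals.

**Statistical mapping.** Per-pixel fixed-effect tests (age group,
pedestrian presence, traffic density) are fitted on participant × condition
cell-mean maps — the summary-statistics equivalent of a mixed model with a
participant random intercept under a balanced design. Multiple comparisons
are handled by a cluster-mass bootstrap: contiguous suprathreshold regions
are tested against the maximum cluster mass over participant-resampled
residual maps.

**Decision statistics.** Participants are clustered by their mean number of
crossing decisions with k-means++ (k = 2, 1000 restarts); groups are
compared with Yuen's test on 20% trimmed means (Welch–Satterthwaite df on
winsorized variances) and Harrell–Davis decile shift functions with
percentile-bootstrap CIs. Trials are dichotomised into low/high traffic
density either at a fixed cut (dense = more than 3 vehicles on screen) or
at the centre of a kernel-density estimate of the per-trial vehicle counts.

**Traffic density.** Vehicles are counted per frame by per-pixel
Gaussian-mixture background subtraction followed by morphological opening
and 8-connected blob labelling; the per-trial density is the maximum
simultaneous count.

## Worked example

The numbered drivers under `analysis/` run the full pipeline on a simulated
cohort (3 age groups × 5 participants × 30 trials of 10 s at 1000 Hz) and
write their tables under `results/`:

```
$ python analysis/01_simulate_cohort.py
simulated 450 trials (30 stimuli x 15 participants) at 1000 Hz, 10 s each
  child_5_10: mean presses/trial 8.09 (generating mean 8.0)
  child_11_15: mean presses/trial 13.03 (generating mean 13.0)
  adult: mean presses/trial 12.97 (generating mean 13.0)

$ python analysis/03_gaze_similarity.py
child_5_10: mean Fisher-z similarity 0.298 (trial range 0.258..0.362)
child_11_15: mean Fisher-z similarity 0.483 (trial range 0.404..0.544)
adult: mean Fisher-z similarity 0.621 (trial range 0.528..0.697)
group ordering by gaze consistency (low to high): child_5_10 < child_11_15 < adult

$ python analysis/05_crossing_decisions.py
k-means on 10 child participants: centroids 8.09 / 13.03 (WCSS 0.12)
Yuen (press counts, upper vs lower cluster): t=31.04, df=178.0, p=9.86e-74, d=1.12
traffic density split: KDE centre 2.98 -> 57% of trials high density
```

The k-means centroids recover the two generating decision-count
distributions (means 8 and 13); the consistency curves order the groups
from most diffuse (youngest children) to most concentrated (adults) gaze;
and the KDE centre of the vehicle counts lands at ~3 cars, the boundary
between the two simulated traffic regimes. `analysis/02_parse_events.py`,
`04_statistical_mapping.py` and `06_traffic_density.py` produce the event
summary tables, the cluster-corrected statistical maps, and the
vehicle-count validation, respectively.

A `gazecross` command-line tool (`simulate`, `parse`, `gsm`, `statmap`,
`decisions`, `traffic`) exposes the same stages for file-based use.

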