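"""Synthetic gaze, cohort, decision and traffic-video generators.

These generators produce every input the analysis pipeline consumes, with
known ground truth:

* :func:`simulate_scanpath` renders a scripted sequence of fixations,
  saccades and smooth pursuits as a 1000 Hz sample stream with per-sample
  ground-truth labels (fixation = static position + Gaussian jitter;
  pursuit = linear drift at a stated angular velocity + jitter; saccade =
  ballistic transition with a triangular velocity profile).
* :func:`simulate_cohort` draws a multi-group cohort: each group has a
  spatial gaze-bias mixture over an "appearing point" region (where vehicles
  enter the scene, upper-left), a sidewalk band (lower frame) and a
  vehicle-following mode (pursuits down the road), plus a normal
  decision-count distribution and log-normal press durations.
* :func:`render_traffic_video` draws moving vehicle rectangles (and
  optionally a slow pedestrian blob) over a static background, returning
  the true per-frame vehicle counts.

Trials default to the experimental design shape: 10 s at 1000 Hz, 100
trials per participant, on a 1920x1080 screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, ScreenGeometry
from .io import DecisionRecord, GazeRecording, TrialMetadata

__all__ = [
    "ScriptEvent",
    "ScanpathScript",
    "GroupSpec",
    "CohortSpec",
    "Cohort",
    "simulate_scanpath",
    "random_script",
    "simulate_cohort",
    "render_traffic_video",
    "DEFAULT_COHORT",
]


@dataclass
class ScriptEvent:
    """One scripted oculomotor event.

    For fixations ``position`` is the (x, y) anchor in px.  For pursuits
    ``position`` is the start point, ``velocity_deg_s`` the angular speed
    and ``heading_deg`` the direction of motion (0 = rightward, 90 = down).
    Saccade events carry only a duration; their trajectory is the ballistic
    transition from the previous event's end point to the next event's
    start point.
    """

    label: str  # fixation | saccade | pursuit
    duration_ms: float
    position: tuple[float, float] | None = None
    velocity_deg_s: float = 0.0
    heading_deg: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("fixation", "saccade", "pursuit"):
            raise ValueError(f"unknown script label {self.label!r}")
        if self.duration_ms <= 0:
            raise ValueError("event durations must be positive")


@dataclass
class ScanpathScript:
    events: list[ScriptEvent]
    jitter_sd_px: float = 0.5
    rate_hz: float = 1000.0
    duration_ms: float = 10_000.0

    def __post_init__(self) -> None:
        total = sum(e.duration_ms for e in self.events)
        if abs(total - self.duration_ms) > 1e-6:
            raise ValueError(
                f"script durations sum to {total} ms, expected {self.duration_ms} ms"
            )


def _event_endpoint(ev: ScriptEvent, geometry: ScreenGeometry) -> tuple[float, float]:
    """Where a fixation/pursuit event ends, given its own parameters."""
    assert ev.position is not None
    if ev.label == "fixation":
        return ev.position
    px_per_deg = 1.0 / geometry.deg_per_px("x")
    speed_px_ms = ev.velocity_deg_s * px_per_deg / 1000.0
    th = np.deg2rad(ev.heading_deg)
    return (
        ev.position[0] + speed_px_ms * ev.duration_ms * np.cos(th),
        ev.position[1] + speed_px_ms * ev.duration_ms * np.sin(th),
    )


def simulate_scanpath(
    script: ScanpathScript,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sim",
    trial_id: str = "trial",
) -> tuple[GazeRecording, np.ndarray]:
    """Render a script to 1000 Hz samples with ground-truth labels.

    Saccades follow a triangular velocity profile between the surrounding
    events' endpoints.  Returns ``(recording, labels)`` where ``labels`` is a
    per-sample array of {"fixation", "saccade", "pursuit"} strings.
    """
    rng = np.random.default_rng(seed)
    dt = 1000.0 / script.rate_hz
    n = int(round(script.duration_ms / dt))
    t = np.arange(n) * dt
    x = np.empty(n)
    y = np.empty(n)
    labels = np.empty(n, dtype=object)

    events = script.events
    # resolve saccade start/end points from neighbours
    i0 = 0
    pos = None
    for k, ev in enumerate(events):
        n_ev = int(round(ev.duration_ms / dt))
        n_ev = min(n_ev, n - i0)
        sl = slice(i0, i0 + n_ev)
        tt = (np.arange(n_ev) + 0.5) * dt
        if ev.label == "fixation":
            cx, cy = ev.position
            x[sl] = cx
            y[sl] = cy
            pos = (cx, cy)
        elif ev.label == "pursuit":
            sx, sy = ev.position
            px_per_deg = 1.0 / geometry.deg_per_px("x")
            v = ev.velocity_deg_s * px_per_deg / 1000.0
            th = np.deg2rad(ev.heading_deg)
            x[sl] = sx + v * tt * np.cos(th)
            y[sl] = sy + v * tt * np.sin(th)
            pos = _event_endpoint(ev, geometry)
        else:  # saccade: ballistic move from pos to next event's start
            if pos is None:
                raise ValueError("script may not start with a saccade")
            nxt = next((e for e in events[k + 1 :] if e.position is not None), None)
            if nxt is None:
                raise ValueError("script may not end with a saccade")
            ex, ey = nxt.position
            # triangular velocity profile -> smoothstep-like displacement
            u = tt / ev.duration_ms
            s = np.where(u < 0.5, 2 * u**2, 1 - 2 * (1 - u) ** 2)
            x[sl] = pos[0] + (ex - pos[0]) * s
            y[sl] = pos[1] + (ey - pos[1]) * s
            pos = (ex, ey)
        labels[sl] = ev.label
        i0 += n_ev
    if i0 < n:  # rounding remainder: hold last position
        x[i0:], y[i0:] = pos
        labels[i0:] = events[-1].label

    x += rng.normal(0.0, script.jitter_sd_px, n)
    y += rng.normal(0.0, script.jitter_sd_px, n)
    np.clip(x, 0, geometry.width_px - 1, out=x)
    np.clip(y, 0, geometry.height_px - 1, out=y)

    rec = GazeRecording(
        participant_id=participant_id,
        trial_id=trial_id,
        t=t,
        x=x,
        y=y,
        valid=np.ones(n, dtype=bool),
        rate_hz=script.rate_hz,
    )
    return rec, labels


# ---------------------------------------------------------------------------
# cohort generation

#: Region centres in px on the default 1920x1080 screen: the road's
#: upper-left vehicle entry point and the lower sidewalk band.
APPEARING_POINT = (380.0, 360.0)
SIDEWALK_BAND = (960.0, 880.0)
ROAD_HEADING_DEG = 25.0  # direction vehicles travel: rightward and downward


@dataclass
class GroupSpec:
    """Generating parameters for one age group.

    ``bias`` is the probability mass over (appearing-point fixations,
    sidewalk fixations, vehicle-following pursuits); ``decision_mean`` and
    ``decision_sd`` parameterise the per-trial press-count normal;
    ``scatter_px`` spreads fixation anchors around the region centres
    (larger = more diffuse gaze).
    """

    name: str
    n_participants: int = 10
    bias: tuple[float, float, float] = (0.6, 0.2, 0.2)
    scatter_px: float = 80.0
    decision_mean: float = 13.0
    decision_sd: float = 1.0
    pedestrian_sidewalk_boost: float = 0.1

    def __post_init__(self) -> None:
        if abs(sum(self.bias) - 1.0) > 1e-9:
            raise ValueError("bias mixture weights must sum to 1")


@dataclass
class CohortSpec:
    groups: list[GroupSpec]
    n_trials: int = 100
    trial_duration_ms: float = 10_000.0
    pedestrian_fraction: float = 0.5
    vehicle_count_means: tuple[float, float] = (1.5, 5.5)  # low / high regimes
    jitter_sd_px: float = 0.5


#: Cohort emulating the study's three age groups.  Decision-count means/SDs
#: for the two child groups are the printed cluster parameters (8 +/- 1 and
#: 13 +/- 1); adults share the older children's distribution, matching the
#: reported equivalence of those groups.  Spatial bias tightens with age.
DEFAULT_COHORT = CohortSpec(
    groups=[
        GroupSpec("child_5_10", 10, (0.40, 0.35, 0.25), 160.0, 8.0, 1.0, 0.25),
        GroupSpec("child_11_15", 10, (0.70, 0.15, 0.15), 100.0, 13.0, 1.0, 0.10),
        GroupSpec("adult", 10, (0.80, 0.10, 0.10), 70.0, 13.0, 1.0, 0.05),
    ]
)


@dataclass
class Cohort:
    """Everything simulate_cohort produces, keyed for downstream stages."""

    recordings: dict[tuple[str, str], GazeRecording]
    labels: dict[tuple[str, str], np.ndarray]
    metadata: list[TrialMetadata]
    decisions: list[DecisionRecord]
    design: pd.DataFrame  # participant_id, trial_id, age_group, pedestrian_present, n_vehicles


_MIN_SACCADE_AMP_PX = 180.0  # keeps simulated saccade peaks well above 200 deg/s


def _draw_anchor(
    rng: np.random.Generator,
    centre: tuple[float, float],
    scatter: float,
    prev: tuple[float, float] | None,
    geometry: ScreenGeometry,
) -> tuple[float, float]:
    """Anchor near ``centre``, pushed away from ``prev`` so the connecting
    saccade has a comfortably supra-threshold amplitude."""
    margin = 40.0
    for _ in range(8):
        ax = float(np.clip(centre[0] + rng.normal(0, scatter), margin, geometry.width_px - margin))
        ay = float(np.clip(centre[1] + rng.normal(0, scatter), margin, geometry.height_px - margin))
        if prev is None or np.hypot(ax - prev[0], ay - prev[1]) >= _MIN_SACCADE_AMP_PX:
            return ax, ay
    # fall back: place at fixed distance in a random direction from prev
    th = rng.uniform(0, 2 * np.pi)
    r = _MIN_SACCADE_AMP_PX * 1.3
    ax = float(np.clip(prev[0] + r * np.cos(th), margin, geometry.width_px - margin))
    ay = float(np.clip(prev[1] + r * np.sin(th), margin, geometry.height_px - margin))
    return ax, ay


def random_script(
    rng: np.random.Generator,
    group: GroupSpec,
    pedestrian_present: int = 0,
    duration_ms: float = 10_000.0,
    jitter_sd_px: float = 0.5,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
) -> ScanpathScript:
    """Draw one trial's scripted scanpath from a group's spatial mixture.

    Consecutive fixation/pursuit events are always joined by a saccade whose
    amplitude is at least ~180 px, so the simulated velocity trace cleanly
    separates events.  Pursuits start near the vehicle appearing point and
    run down the road heading; their duration is capped so the path stays
    on screen.
    """
    w_app, w_side, w_follow = group.bias
    w_side = min(w_side + group.pedestrian_sidewalk_boost * pedestrian_present, 1.0 - w_follow)
    w_app = 1.0 - w_side - w_follow
    px_per_deg = 1.0 / geometry.deg_per_px("x")
    margin = 40.0

    events: list[ScriptEvent] = []
    remaining = duration_ms
    pos: tuple[float, float] | None = None
    while remaining > 600.0:
        kind = rng.choice(["appearing", "sidewalk", "follow"], p=[w_app, w_side, w_follow])
        if kind == "follow":
            start = _draw_anchor(rng, APPEARING_POINT, group.scatter_px / 2, pos, geometry)
            speed_deg = float(rng.uniform(8, 16))
            heading = ROAD_HEADING_DEG + float(rng.normal(0, 5))
            v_px_ms = speed_deg * px_per_deg / 1000.0
            th = np.deg2rad(heading)
            # cap duration so the path stays inside the screen margins
            dx, dy = np.cos(th), np.sin(th)
            lim_x = ((geometry.width_px - margin - start[0]) / dx) if dx > 0 else np.inf
            lim_y = ((geometry.height_px - margin - start[1]) / dy) if dy > 0 else np.inf
            max_dur = min(lim_x, lim_y) / v_px_ms
            dur = float(min(rng.uniform(400, 1200), max_dur, remaining - 400))
            if dur < 300:
                continue
            ev = ScriptEvent("pursuit", dur, position=start, velocity_deg_s=speed_deg, heading_deg=heading)
        else:
            centre = APPEARING_POINT if kind == "appearing" else SIDEWALK_BAND
            dur = float(min(rng.uniform(250, 900), remaining - 400))
            if pos is not None and events and events[-1].label == "fixation":
                # tight spatial bias: nearby anchors continue the same fixation
                anchor = (
                    float(np.clip(centre[0] + rng.normal(0, group.scatter_px), margin, geometry.width_px - margin)),
                    float(np.clip(centre[1] + rng.normal(0, group.scatter_px), margin, geometry.height_px - margin)),
                )
                if np.hypot(anchor[0] - pos[0], anchor[1] - pos[1]) < _MIN_SACCADE_AMP_PX:
                    events[-1].duration_ms += dur
                    remaining -= dur
                    continue
            anchor = _draw_anchor(rng, centre, group.scatter_px, pos, geometry)
            ev = ScriptEvent("fixation", dur, position=anchor)
        if pos is not None:
            amp = float(np.hypot(ev.position[0] - pos[0], ev.position[1] - pos[1]))
            sacc_dur = float(np.clip(0.2 * amp, 30.0, 60.0))
            events.append(ScriptEvent("saccade", sacc_dur))
            remaining -= sacc_dur
        events.append(ev)
        remaining -= ev.duration_ms
        pos = _event_endpoint(ev, geometry)
    # closing fixation absorbs the remainder
    if events and events[-1].label == "fixation":
        events[-1].duration_ms += remaining
    else:
        anchor = _draw_anchor(rng, APPEARING_POINT, group.scatter_px, pos, geometry)
        if pos is not None:
            amp = float(np.hypot(anchor[0] - pos[0], anchor[1] - pos[1]))
            sacc_dur = float(np.clip(0.2 * amp, 30.0, 60.0))
            events.append(ScriptEvent("saccade", sacc_dur))
            remaining -= sacc_dur
        events.append(ScriptEvent("fixation", remaining, position=anchor))
    return ScanpathScript(events=events, jitter_sd_px=jitter_sd_px, duration_ms=duration_ms)


def simulate_cohort(
    spec: CohortSpec = DEFAULT_COHORT,
    seed: int = 0,
    geometry: ScreenGeometry = DEFAULT_GEOMETRY,
) -> Cohort:
    """Draw a full cohort: scanpaths, trial metadata, decisions and design table.

    Trial metadata are shared across participants (every participant sees the
    same stimulus set).  Decision counts per trial are drawn from the group's
    normal distribution, rounded and floored at zero; press durations are
    log-normal around ~1 s.
    """
    rng = np.random.default_rng(seed)
    # shared stimulus set
    metadata = []
    for j in range(spec.n_trials):
        ped = int(rng.random() < spec.pedestrian_fraction)
        lam = spec.vehicle_count_means[j % 2]
        nveh = int(rng.poisson(lam))
        metadata.append(TrialMetadata(trial_id=f"T{j:03d}", pedestrian_present=ped, n_vehicles=nveh))

    recordings: dict[tuple[str, str], GazeRecording] = {}
    labels: dict[tuple[str, str], np.ndarray] = {}
    decisions: list[DecisionRecord] = []
    rows = []
    for g in spec.groups:
        for i in range(g.n_participants):
            pid = f"{g.name}_p{i:02d}"
            for meta in metadata:
                script = random_script(
                    rng, g, meta.pedestrian_present, spec.trial_duration_ms, spec.jitter_sd_px, geometry
                )
                rec, lab = simulate_scanpath(
                    script, geometry, rng, participant_id=pid, trial_id=meta.trial_id
                )
                recordings[(pid, meta.trial_id)] = rec
                labels[(pid, meta.trial_id)] = lab
                n_press = max(0, int(round(rng.normal(g.decision_mean, g.decision_sd))))
                durs = [float(v) for v in rng.lognormal(np.log(1000.0), 0.4, n_press)]
                decisions.append(DecisionRecord(pid, meta.trial_id, n_press, durs))
                rows.append(
                    {
                        "participant_id": pid,
                        "trial_id": meta.trial_id,
                        "age_group": g.name,
                        "pedestrian_present": meta.pedestrian_present,
                        "n_vehicles": meta.n_vehicles,
                    }
                )
    return Cohort(recordings, labels, metadata, decisions, pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# traffic video rendering


def render_traffic_video(
    n_vehicles: int,
    pedestrian_present: bool = False,
    n_frames: int = 120,
    shape: tuple[int, int] = (135, 240),
    seed: int = 0,
    noise_sd: float = 0.01,
    stagger: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Toy road scene: bright rectangles moving along a fixed road line.

    Vehicles enter at a fixed appearing point (upper-left) and travel with
    constant velocity toward the lower-right.  With ``stagger`` the entry
    times are spread so that all vehicles are simultaneously on screen in
    the second half of the clip.  An optional pedestrian is a small slow
    blob drifting along the lower sidewalk band.

    Returns ``(frames, true_counts)``: a (T, H, W) float stack in [0, 1] and
    the true number of vehicles visible in each frame.
    """
    if n_vehicles < 0:
        raise ValueError("n_vehicles must be >= 0")
    rng = np.random.default_rng(seed)
    H, W = shape
    frames = np.empty((n_frames, H, W))
    background = 0.15 + 0.05 * rng.random((H, W))
    veh_h, veh_w = max(6, H // 14), max(10, W // 14)
    entry = np.array([W * 0.05, H * 0.25])
    direction = np.array([1.0, 0.35])
    direction /= np.hypot(*direction)
    speed = (W * 1.1) / n_frames * 1.6  # px/frame; crosses in ~60% of the clip
    if stagger:
        # all vehicles co-occur around frame ~0.65*T
        mid = 0.65 * n_frames
        travel = np.hypot(W, H * 0.4)
        offsets = np.linspace(-0.3, 0.3, max(n_vehicles, 1)) * travel / speed
        t_enter = mid - travel / (2 * speed) + offsets
    else:
        t_enter = rng.uniform(0, n_frames * 0.7, size=n_vehicles)

    true_counts = np.zeros(n_frames, dtype=int)
    for f in range(n_frames):
        img = background.copy()
        for v in range(n_vehicles):
            d = (f - t_enter[v]) * speed
            if d < 0:
                continue
            cx, cy = entry + direction * d
            x0, x1 = int(cx - veh_w / 2), int(cx + veh_w / 2)
            y0, y1 = int(cy - veh_h / 2), int(cy + veh_h / 2)
            if x0 >= W or y0 >= H or x1 <= 0 or y1 <= 0:
                continue
            img[max(y0, 0) : min(y1, H), max(x0, 0) : min(x1, W)] = 0.85 + 0.1 * ((v % 3) / 2)
            true_counts[f] += 1
        if pedestrian_present:
            # pedestrian blob is kept below the default blob-area threshold,
            # so area filtering separates it from vehicles
            px = W * (0.2 + 0.5 * f / n_frames)
            py = H * 0.85
            x0, x1 = int(px - 1), int(px + 2)
            y0, y1 = int(py - 3), int(py + 4)
            img[max(y0, 0) : min(y1, H), max(x0, 0) : min(x1, W)] = 0.6
        img += rng.normal(0, noise_sd, (H, W))
        frames[f] = np.clip(img, 0.0, 1.0)
    return frames, true_counts
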