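"""Record types and plain-text readers/writers.

All on-disk formats are plain text: gaze samples as CSV ``t,x,y,valid``,
event segments as TSV, trial metadata and decisions as CSV, and similarity
matrices as labelled whitespace tables.  Coordinates are 0-based screen
pixels with the origin at the top-left; timestamps are milliseconds; event
intervals are half-open ``[t_start, t_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import ScreenGeometry

__all__ = [
    "FormatError",
    "DataError",
    "GazeRecording",
    "EventSegment",
    "TrialMetadata",
    "DecisionRecord",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_events_tsv",
    "write_events_tsv",
    "read_metadata_csv",
    "write_metadata_csv",
    "read_decisions_csv",
    "write_decisions_csv",
    "read_matrix_txt",
    "write_matrix_txt",
    "read_config",
]


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


class DataError(ValueError):
    """A file parses but violates a data invariant (e.g. non-monotone time)."""


EVENT_LABELS = ("fixation", "saccade", "pursuit", "missing")


@dataclass
class GazeRecording:
    """One trial's raw gaze sample stream.

    ``t`` holds strictly increasing timestamps in ms; ``x``/``y`` screen
    coordinates in pixels; ``valid`` flags blinks/track loss (False rows keep
    their last coordinates but are ignored by all downstream computation).
    """

    participant_id: str
    trial_id: str
    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray
    rate_hz: float = 1000.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.valid) == n):
            raise DataError("t, x, y, valid must have equal lengths")
        if n > 1:
            bad = np.nonzero(np.diff(self.t) <= 0)[0]
            if bad.size:
                raise DataError(
                    f"timestamps not strictly increasing at row index {bad[0] + 1}"
                )
        if n and not np.all(np.isfinite(self.x[self.valid]) & np.isfinite(self.y[self.valid])):
            raise DataError("valid samples must have finite coordinates")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def dt_ms(self) -> float:
        """Nominal sample interval in ms."""
        return 1000.0 / self.rate_hz

    @property
    def duration_ms(self) -> float:
        """Trial duration: span of timestamps plus one nominal interval."""
        if len(self.t) == 0:
            return 0.0
        return float(self.t[-1] - self.t[0]) + self.dt_ms


@dataclass
class EventSegment:
    """A labelled oculomotor event over the half-open interval [t_start, t_end)."""

    trial_id: str
    label: str
    t_start: float
    t_end: float
    mean_x: float
    mean_y: float
    score: float | None = None

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown event label {self.label!r}")
        if not self.t_end > self.t_start:
            raise ValueError("segment must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class TrialMetadata:
    """Per-trial stimulus description."""

    trial_id: str
    pedestrian_present: int
    n_vehicles: int
    density_class: str | None = None

    def __post_init__(self) -> None:
        if self.pedestrian_present not in (0, 1):
            raise ValueError("pedestrian_present must be 0 or 1")
        if self.n_vehicles < 0:
            raise ValueError("n_vehicles must be non-negative")
        if self.density_class not in (None, "low", "high"):
            raise ValueError("density_class must be 'low', 'high' or None")


@dataclass
class DecisionRecord:
    """Crossing decisions for one participant x trial: button-press count and durations."""

    participant_id: str
    trial_id: str
    n_presses: int
    press_durations_ms: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_presses != len(self.press_durations_ms):
            raise ValueError("n_presses must equal len(press_durations_ms)")
        if any(d <= 0 for d in self.press_durations_ms):
            raise ValueError("press durations must be positive")


# ---------------------------------------------------------------------------
# gaze samples


def read_gaze_csv(
    path: str | Path,
    geometry: ScreenGeometry | None = None,
    participant_id: str = "",
    trial_id: str = "",
    rate_hz: float = 1000.0,
) -> GazeRecording:
    """Read a gaze sample CSV with header columns ``t,x,y,valid``.

    ``geometry`` is accepted for interface symmetry (samples are stored in
    pixels and need no conversion on read).
    """
    df = pd.read_csv(path)
    missing = {"t", "x", "y", "valid"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    return GazeRecording(
        participant_id=participant_id or str(df.get("participant_id", pd.Series([""])).iloc[0]),
        trial_id=trial_id or str(df.get("trial_id", pd.Series([""])).iloc[0]),
        t=df["t"].to_numpy(float),
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        valid=df["valid"].to_numpy().astype(bool),
        rate_hz=rate_hz,
    )


def write_gaze_csv(recording: GazeRecording, path: str | Path) -> None:
    pd.DataFrame(
        {
            "t": recording.t,
            "x": recording.x,
            "y": recording.y,
            "valid": recording.valid.astype(int),
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# event segments

_EVENT_COLS = ["trial_id", "label", "t_start_ms", "t_end_ms", "duration_ms", "mean_x", "mean_y", "score"]


def write_events_tsv(segments: Sequence[EventSegment], path: str | Path) -> None:
    """Write time-sorted, non-overlapping segments as TSV; round-trips via read_events_tsv."""
    by_trial: dict[str, list[EventSegment]] = {}
    for s in segments:
        by_trial.setdefault(s.trial_id, []).append(s)
    for trial_segs in by_trial.values():
        trial_segs.sort(key=lambda s: s.t_start)
        for a, b in zip(trial_segs, trial_segs[1:]):
            if b.t_start < a.t_end:
                raise ValueError(
                    f"overlapping segments in trial {a.trial_id!r}: "
                    f"[{a.t_start},{a.t_end}) and [{b.t_start},{b.t_end})"
                )
    rows = [
        {
            "trial_id": s.trial_id,
            "label": s.label,
            "t_start_ms": s.t_start,
            "t_end_ms": s.t_end,
            "duration_ms": s.duration,
            "mean_x": s.mean_x,
            "mean_y": s.mean_y,
            "score": "" if s.score is None else repr(s.score),
        }
        for s in sorted(segments, key=lambda s: (s.trial_id, s.t_start))
    ]
    pd.DataFrame(rows, columns=_EVENT_COLS).to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> list[EventSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"trial_id": str}, float_precision="round_trip")
    missing = set(_EVENT_COLS[:-1]) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        out.append(
            EventSegment(
                trial_id=str(row.trial_id),
                label=row.label,
                t_start=float(row.t_start_ms),
                t_end=float(row.t_end_ms),
                mean_x=float(row.mean_x),
                mean_y=float(row.mean_y),
                score=None if score is None or pd.isna(score) else float(score),
            )
        )
    return out


# ---------------------------------------------------------------------------
# trial metadata and decisions


def write_metadata_csv(metadata: Sequence[TrialMetadata], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": m.trial_id,
                "pedestrian_present": m.pedestrian_present,
                "n_vehicles": m.n_vehicles,
                "density_class": m.density_class or "",
            }
            for m in metadata
        ],
        columns=["trial_id", "pedestrian_present", "n_vehicles", "density_class"],
    ).to_csv(path, index=False)


def read_metadata_csv(path: str | Path) -> list[TrialMetadata]:
    df = pd.read_csv(path, dtype={"trial_id": str}, keep_default_na=False)
    missing = {"trial_id", "pedestrian_present", "n_vehicles"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    return [
        TrialMetadata(
            trial_id=str(r.trial_id),
            pedestrian_present=int(r.pedestrian_present),
            n_vehicles=int(r.n_vehicles),
            density_class=(str(r.density_class) or None) if "density_class" in df.columns else None,
        )
        for r in df.itertuples(index=False)
    ]


def write_decisions_csv(decisions: Sequence[DecisionRecord], path: str | Path) -> None:
    """One row per record; durations joined by ';' so the file stays one-row-per-trial."""
    pd.DataFrame(
        [
            {
                "participant_id": d.participant_id,
                "trial_id": d.trial_id,
                "n_presses": d.n_presses,
                "press_durations_ms": ";".join(repr(float(v)) for v in d.press_durations_ms),
            }
            for d in decisions
        ],
        columns=["participant_id", "trial_id", "n_presses", "press_durations_ms"],
    ).to_csv(path, index=False)


def read_decisions_csv(path: str | Path) -> list[DecisionRecord]:
    df = pd.read_csv(path, dtype={"participant_id": str, "trial_id": str}, keep_default_na=False)
    missing = {"participant_id", "trial_id", "n_presses", "press_durations_ms"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing required column(s) {sorted(missing)}")
    out = []
    for r in df.itertuples(index=False):
        durs = [float(v) for v in str(r.press_durations_ms).split(";") if v]
        out.append(
            DecisionRecord(
                participant_id=str(r.participant_id),
                trial_id=str(r.trial_id),
                n_presses=int(r.n_presses),
                press_durations_ms=durs,
            )
        )
    return out


# ---------------------------------------------------------------------------
# labelled matrices


def write_matrix_txt(matrix: np.ndarray, labels: Sequence[str], path: str | Path) -> None:
    """Labelled square matrix as whitespace-separated text (row/col labels)."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1] or m.shape[0] != len(labels):
        raise ValueError("matrix must be square with one label per row")
    pd.DataFrame(m, index=list(labels), columns=list(labels)).to_csv(path, sep="\t")


def read_matrix_txt(path: str | Path) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(float), [str(c) for c in df.index]


# ---------------------------------------------------------------------------
# configuration


def read_config(path: str | Path) -> dict[str, str]:
    """Flat ``key = value`` text config; '#' starts a comment; values are strings."""
    out: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise FormatError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
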