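"""Trial alignment: speed, shuttle detection, windows, condition averages.

Turns tracking and tone signals into event-aligned trial tensors.  Times
are seconds on the subject's concatenated session clock; all signals are
sampled at 5 Hz.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import ARENA_MIDLINES, FS, SubjectData

logger = logging.getLogger(__name__)

#: The three most stable tracking points, averaged for the overall speed.
STABLE_POINTS = ("left ear", "right ear", "miniscope bottom")

#: Pseudoshuttle latencies are matched to avoid-shuttle latencies within
#: these bounds (s after tone start).
LATENCY_BOUNDS = (3.0, 9.0)


@dataclass
class AlignedTrialTensor:
    """Trials x features x time window, aligned to one event."""

    data: np.ndarray
    trial_ids: np.ndarray  # rows of the trial table that survived
    alignment: str  # 'tone-start' | 'shuttle-start' | 'tone-end'
    window: tuple[float, float]
    fs: float = FS

    @property
    def align_index(self) -> int:
        """Sample index of the alignment event within the window."""
        return int(round(-self.window[0] * self.fs))

    @property
    def times(self) -> np.ndarray:
        n = self.data.shape[2]
        return self.window[0] + np.arange(n) / self.fs


def instantaneous_speed(
    tracking: np.ndarray,
    point_labels: tuple[str, ...],
    fs: float = FS,
    points: tuple[str, ...] = STABLE_POINTS,
) -> np.ndarray:
    """Overall animal speed from the centroid of the stable tracked points.

    speed(t) = Euclidean displacement of the centroid between samples t-1
    and t, divided by the step duration; speed(0) = 0.  Units: px/s.
    """
    missing = [p for p in points if p not in point_labels]
    if missing:
        raise ValueError(f"tracking points missing: {missing}")
    idx = [point_labels.index(p) for p in points]
    centroid = np.asarray(tracking, dtype=float)[idx].mean(axis=0)  # time x 2
    speed = np.zeros(centroid.shape[0])
    speed[1:] = np.linalg.norm(np.diff(centroid, axis=0), axis=1) * fs
    return speed


def per_point_speed(
    tracking: np.ndarray, fs: float = FS
) -> np.ndarray:
    """Per-point speed traces (points x time), the video-decoder features."""
    tracking = np.asarray(tracking, dtype=float)
    speed = np.zeros(tracking.shape[:2])
    speed[:, 1:] = np.linalg.norm(np.diff(tracking, axis=1), axis=2) * fs
    return speed


def detect_shuttle_start(
    speed: np.ndarray, crossing_time: float, fs: float = FS
) -> float:
    """Refine a detected midline-crossing time to the shuttle start.

    Returns the timepoint with the maximal increase in instantaneous speed
    within the 2 s window before the crossing; ties resolve to the
    earliest such timepoint.
    """
    i_cross = int(round(crossing_time * fs))
    i_lo = i_cross - int(round(2.0 * fs))
    if i_lo < 0:
        raise ValueError("crossing_time must be at least 2 s after trace start")
    window = np.asarray(speed, dtype=float)[i_lo : i_cross + 1]
    increases = np.diff(window)  # increase at step t = speed[t+1] - speed[t]
    return (i_lo + int(np.argmax(increases))) / fs


def sample_pseudoshuttle(
    avoid_latencies: np.ndarray,
    n_error: int,
    rng: np.random.Generator,
    bounds: tuple[float, float] = LATENCY_BOUNDS,
) -> np.ndarray:
    """Sample error-trial alignment latencies matched to avoid latencies.

    Draws ``n_error`` latencies with replacement from the empirical
    distribution of avoid-shuttle latencies restricted to ``bounds``, so
    that trial length carries no information about trial type.
    """
    lat = np.asarray(avoid_latencies, dtype=float)
    eligible = lat[(lat >= bounds[0]) & (lat <= bounds[1])]
    if eligible.size == 0:
        raise ValueError(f"no avoid latencies within {bounds}")
    return rng.choice(eligible, size=n_error, replace=True)


def assign_pseudoshuttles(
    trials: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Fill error-trial align_time with sampled pseudoshuttle starts.

    Avoid latencies are pooled over the table (per subject); a fresh
    assignment is drawn per analysis repetition.
    """
    trials = trials.copy()
    out = []
    for _, sub in trials.groupby("subject", sort=False):
        sub = sub.copy()
        avoid = sub[sub["type"] == "avoid"]
        latencies = (avoid["align_time"] - avoid["tone_on"]).to_numpy()
        err = sub["type"] == "error"
        if err.any():
            pseudo = sample_pseudoshuttle(latencies, int(err.sum()), rng)
            sub.loc[err, "align_time"] = sub.loc[err, "tone_on"] + pseudo
        out.append(sub)
    return pd.concat(out).sort_index()


def extract_windows(
    traces: np.ndarray,
    trials: pd.DataFrame,
    alignment: str,
    window: tuple[float, float],
    fs: float = FS,
) -> AlignedTrialTensor:
    """Slice feature x time traces into an aligned trial tensor.

    ``alignment`` is 'tone-start', 'shuttle-start' or 'tone-end'.  When
    aligning to shuttle start with a window reaching 3 s or more into the
    past, avoid trials that shuttled less than 3 s after tone start are
    discarded (their window would otherwise include pre-tone data).
    Trials whose window exceeds the recording are dropped with a log entry.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    if alignment == "tone-start":
        align_times = trials["tone_on"].to_numpy(dtype=float)
    elif alignment == "shuttle-start":
        align_times = trials["align_time"].to_numpy(dtype=float)
    elif alignment == "tone-end":
        align_times = trials["tone_off"].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown alignment {alignment!r}")

    keep = np.isfinite(align_times)
    if alignment == "shuttle-start" and window[0] <= -3.0:
        latency = align_times - trials["tone_on"].to_numpy(dtype=float)
        is_avoid = (trials["type"] == "avoid").to_numpy()
        keep &= ~(is_avoid & (latency < 3.0))

    n_w = int(round((window[1] - window[0]) * fs))
    chunks, ids = [], []
    for i in np.flatnonzero(keep):
        start = int(round((align_times[i] + window[0]) * fs))
        if start < 0 or start + n_w > traces.shape[1]:
            logger.info("trial %s dropped: window outside recording", i)
            continue
        chunks.append(traces[:, start : start + n_w])
        ids.append(i)
    data = (
        np.stack(chunks) if chunks else np.empty((0, traces.shape[0], n_w))
    )
    return AlignedTrialTensor(
        data=data,
        trial_ids=np.asarray(ids, dtype=int),
        alignment=alignment,
        window=window,
        fs=fs,
    )


def condition_averages(
    tensors: dict[str, np.ndarray]
) -> dict[str, np.ndarray]:
    """Average trial tensors per condition into features x time matrices.

    Input arrays are trials x features x time (for avoid/error conditions
    the tone-start and shuttle-start windows are concatenated along time
    before this step, giving 40 samples = 8 s at 5 Hz).
    """
    empty = [c for c, x in tensors.items() if len(x) == 0]
    if empty:
        raise ValueError(f"conditions with no trials: {empty}")
    return {c: np.asarray(x, dtype=float).mean(axis=0) for c, x in tensors.items()}


def classify_shuttle(
    tracking: np.ndarray,
    point_labels: tuple[str, ...],
    event_time: float,
    arena_midlines: tuple[float, float] = ARENA_MIDLINES,
    fs: float = FS,
    window: tuple[float, float] = (-1.0, 2.0),
) -> str:
    """Classify a shuttle as 'X', 'Y' or 'XY' by the midlines it crosses.

    Any sign change of the centroid's distance to a midline within the
    event window counts as a crossing of that midline.
    """
    idx = [point_labels.index(p) for p in STABLE_POINTS]
    centroid = np.asarray(tracking, dtype=float)[idx].mean(axis=0)
    i0 = int(round((event_time + window[0]) * fs))
    i1 = int(round((event_time + window[1]) * fs))
    if i0 < 0 or i1 > centroid.shape[0]:
        raise ValueError("event window outside recording")
    seg = centroid[i0:i1]
    crossed_x = np.any(np.diff(np.sign(seg[:, 0] - arena_midlines[0])) != 0)
    crossed_y = np.any(np.diff(np.sign(seg[:, 1] - arena_midlines[1])) != 0)
    if crossed_x and crossed_y:
        return "XY"
    if crossed_x:
        return "X"
    if crossed_y:
        return "Y"
    raise ValueError(f"no midline crossing within {window} s of t={event_time}")


def sample_iti_random_times(
    subject: SubjectData,
    n: int,
    rng: np.random.Generator,
    margin_s: float = 4.0,
) -> np.ndarray:
    """Sample event-free ITI timepoints (the null class for ITI decoding).

    Candidate samples lie at least ``margin_s`` from every tone window and
    every shuttle event, and ``margin_s`` from the recording edges, so a
    4 s window around each returned time contains no event.
    """
    t = np.arange(subject.n_samples) / subject.fs
    ok = np.ones(subject.n_samples, dtype=bool)
    ok[t < margin_s] = False
    ok[t > t[-1] - margin_s] = False
    for _, row in subject.trials.iterrows():
        if np.isfinite(row["tone_on"]):
            ok &= ~((t > row["tone_on"] - margin_s) & (t < row["tone_off"] + margin_s))
        if np.isfinite(row["align_time"]):
            ok &= ~(np.abs(t - row["align_time"]) < margin_s)
    candidates = t[ok]
    if candidates.size == 0:
        raise ValueError("no event-free ITI samples available")
    if candidates.size < n:
        warnings.warn(
            f"only {candidates.size} event-free samples for {n} requested; "
            "sampling with replacement",
            stacklevel=2,
        )
        return rng.choice(candidates, size=n, replace=True)
    return rng.choice(candidates, size=n, replace=False)
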