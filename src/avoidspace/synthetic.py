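"""Synthetic multi-subject cohorts with planted low-dimensional structure.

The generator emulates a two-task active-avoidance paradigm recorded with
head-mounted calcium imaging: each subject contributes a cells x time
:math:`\\Delta F/F` trace matrix at 5 Hz, a five-point body-tracking stream,
a binary warning-tone signal and a trial table.  Population activity is
built as a small number of shared latent time courses mixed into cells
through dense random loadings (mixed selectivity) plus Gaussian noise, so
every downstream stage — subject alignment, decoding, coding-dimension
decomposition — can be validated by parameter recovery against the planted
ground truth.

Planted latents (defaults):

``motion-1``, ``motion-2``
    Ramps peaking at shuttle start, present for *every* shuttle event
    (avoidance shuttles and spontaneous inter-trial-interval shuttles).
``avoid-1``
    Ramp present only in avoid trials, shared across both tasks.
``avoid-2``
    Ramp present only in task-2 avoid trials.
``tone``
    Step signal during tone presentation whose amplitude starts to decay a
    fixed number of time steps after shuttle start (the behaviour-gated
    drop of the tone representation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

FS = 5.0
"""Sampling rate of traces, tracking and tone signals (Hz)."""

DT = 1.0 / FS

CONDITIONS = (
    "avoid-task1",
    "avoid-task2",
    "error-task1",
    "error-task2",
    "ITI-shuttle",
    "ITI-random",
)

#: Tracking-point labels; the first three are the stable points used for
#: the overall speed estimate.
POINT_LABELS = ("left ear", "right ear", "miniscope bottom", "nose", "tail base")

ARENA_SIZE = (200.0, 200.0)
ARENA_MIDLINES = (100.0, 100.0)


@dataclass
class LatentSpec:
    """Configuration of the planted latent signals.

    Parameters
    ----------
    n_motion, n_avoid_shared, n_avoid_task2, n_tone
        Number of latents of each family.  The canonical configuration is
        2 + 1 + 1 + 1 = 5 latents.
    ramp_onset_s
        Seconds before shuttle start at which motion/avoid ramps begin.
    tone_drop_lag_steps
        Time steps (at 5 Hz) after shuttle start at which the tone latent
        starts to decay; the default of 2 steps corresponds to 400 ms.
    tone_drop_decay_steps
        Length of the linear decay of the tone latent, in time steps.  The
        default of 11 steps (2.2 s) puts the decrease at 1.2 s after
        shuttle start near 36%, the magnitude of the behaviour-gated tone
        suppression this latent emulates.
    effect_size
        Peak amplitude of every latent (dimensionless, trace units).
    noise_sigma
        Standard deviation of the i.i.d. Gaussian trace noise.  With
        column-orthonormalised loadings over 60 cells, a unit effect size
        spreads to per-cell event amplitudes of about 0.13; the default
        of 0.15 therefore puts single-cell transients at roughly unit
        SNR — visible in individual traces, as validated cells are.
    motion_background_sigma
        S.d. (relative to the shuttle-ramp peak) of the smooth background
        fluctuation added to the motion latents throughout every session.
        Animals locomote continuously, not only during shuttles; this
        keeps motion activity present in all conditions, so that motion is
        an imperfect proxy for trial outcome — as it is in vivo.
    motion_background_smooth_steps
        Gaussian smoothing s.d. (in 200-ms steps) of that background
        process; the default of 5 steps gives ~1 s fluctuations.
    """

    n_motion: int = 2
    n_avoid_shared: int = 1
    n_avoid_task2: int = 1
    n_tone: int = 1
    ramp_onset_s: float = 2.0
    tone_drop_lag_steps: int = 2
    tone_drop_decay_steps: int = 11
    effect_size: float = 1.0
    noise_sigma: float = 0.15
    motion_background_sigma: float = 0.4
    motion_background_smooth_steps: float = 5.0

    def __post_init__(self) -> None:
        for name in ("n_motion", "n_avoid_shared", "n_avoid_task2", "n_tone"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def n_latents(self) -> int:
        return self.n_motion + self.n_avoid_shared + self.n_avoid_task2 + self.n_tone

    @property
    def labels(self) -> list[str]:
        labels = [f"motion-{i + 1}" for i in range(self.n_motion)]
        labels += [f"avoid-{i + 1}" for i in range(self.n_avoid_shared)]
        labels += [
            f"avoid-{self.n_avoid_shared + i + 1}" for i in range(self.n_avoid_task2)
        ]
        labels += ["tone" if self.n_tone == 1 else f"tone-{i + 1}" for i in range(self.n_tone)]
        return labels


@dataclass
class SubjectData:
    """One subject's recordings on a single concatenated session clock."""

    subject: str
    traces: np.ndarray  # cells x time, ΔF/F at 5 Hz
    tracking: np.ndarray  # points x time x 2 (pixels)
    point_labels: tuple[str, ...]
    tone: np.ndarray  # time, binary
    trials: pd.DataFrame
    session_bounds: dict[int, tuple[int, int]]  # day -> [start, stop) sample index
    fs: float = FS

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_samples(self) -> int:
        return self.traces.shape[1]


@dataclass
class CohortDataset:
    subjects: list[SubjectData]
    fs: float = FS


@dataclass
class GroundTruth:
    """Planted structure of a synthetic cohort."""

    loadings: list[np.ndarray]  # per subject, cells x latents, orthonormal columns
    latent_labels: list[str]
    latents: list[np.ndarray]  # per subject, latents x time on the session clock
    spec: LatentSpec
    seed: int
    condition_timecourses: dict[str, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# latent waveforms


def _ramp(t: np.ndarray, peak: float, rise_s: float, decay_s: float) -> np.ndarray:
    """Piecewise-linear ramp: 0 -> 1 over ``rise_s``, peak at ``peak``, back to 0."""
    return np.interp(t, [peak - rise_s, peak, peak + decay_s], [0.0, 1.0, 0.0])


def _motion_shapes(spec: LatentSpec, t: np.ndarray, shuttle: float) -> np.ndarray:
    """Motion-latent waveforms; shapes differ so the latents stay independent."""
    out = np.zeros((spec.n_motion, t.size))
    for i in range(spec.n_motion):
        rise = spec.ramp_onset_s / (i + 1.0)
        decay = 1.0 + i
        out[i] = _ramp(t, shuttle, rise, decay)
    return out


def _tone_shape(
    spec: LatentSpec,
    t: np.ndarray,
    tone_on: float,
    tone_off: float,
    shuttle: float | None,
) -> np.ndarray:
    step = ((t >= tone_on) & (t < tone_off)).astype(float)
    if shuttle is None:
        return step
    # behaviour-gated drop: flat until `lag` steps after shuttle start,
    # then linear decay to zero over `decay` steps
    lag = spec.tone_drop_lag_steps * DT
    decay = spec.tone_drop_decay_steps * DT
    envelope = np.interp(
        t, [shuttle + lag, shuttle + lag + decay], [1.0, 0.0], left=1.0, right=0.0
    )
    return step * envelope


def generate_latent_timecourses(
    spec: LatentSpec,
    condition: str,
    latency_s: float = 6.0,
    tone_duration_s: float = 10.0,
) -> np.ndarray:
    """Canonical latent time courses for one trial of a given condition.

    For trial conditions (``avoid-*``, ``error-*``) the time grid runs from
    2 s before tone start to 4 s after the nominal tone end, at 5 Hz, with
    the tone starting at time 0.  For the ITI conditions the grid covers
    [-4 s, 4 s) around shuttle start.

    Parameters
    ----------
    condition
        One of :data:`CONDITIONS`.
    latency_s
        Shuttle latency after tone start (trial conditions only).

    Returns
    -------
    ndarray of shape (n_latents, n_steps)
        Rows ordered motion, avoid-shared, avoid-task2, tone.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}; expected one of {CONDITIONS}")

    if condition in ("ITI-shuttle", "ITI-random"):
        t = np.arange(-4.0, 4.0 - 1e-9, DT)
        out = np.zeros((spec.n_latents, t.size))
        if condition == "ITI-shuttle":
            out[: spec.n_motion] = _motion_shapes(spec, t, shuttle=0.0)
        return spec.effect_size * out

    t = np.arange(-2.0, tone_duration_s + 4.0 - 1e-9, DT)
    out = np.zeros((spec.n_latents, t.size))
    is_avoid = condition.startswith("avoid")
    task2 = condition.endswith("task2")

    if is_avoid:
        shuttle = latency_s
        tone_off = min(shuttle + 1.0, tone_duration_s)
    else:
        shuttle = None  # error trials contain no shuttle motion
        tone_off = tone_duration_s

    i = 0
    if is_avoid:
        out[: spec.n_motion] = _motion_shapes(spec, t, shuttle)
    i += spec.n_motion
    if is_avoid:
        for j in range(spec.n_avoid_shared):
            out[i + j] = _ramp(t, shuttle, spec.ramp_onset_s, 1.0)
    i += spec.n_avoid_shared
    if is_avoid and task2:
        # the task-2-specific signal has its own temporal profile (distinct
        # coding dimensions carry distinct dynamics); see _ramp shapes
        for j in range(spec.n_avoid_task2):
            out[i + j] = _ramp(t, shuttle, spec.ramp_onset_s / 2.0, 1.5)
    i += spec.n_avoid_task2
    for j in range(spec.n_tone):
        out[i + j] = _tone_shape(spec, t, 0.0, tone_off, shuttle)
    return spec.effect_size * out


# ---------------------------------------------------------------------------
# cohort generation

_SMOOTHSTEP_DUR = 1.4  # shuttle crossing duration (s)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    u = np.clip(u, 0.0, 1.0)
    return u * u * (3.0 - 2.0 * u)


def _default_days() -> dict[int, int]:
    """Default session layout: the in-task days the analyses consume.

    Mirrors the paradigm's phase structure — two task-1 sessions (days 3
    and 4) and five task-2 sessions (days 5-9).  The habituation and
    extinction days are omitted: no analysis stage reads them, and the
    2:5 imbalance between tasks is itself a feature of the paradigm (it
    shapes which avoidance direction the pooled decoders find first).
    """
    return {3: 1, 4: 1, 5: 2, 6: 2, 7: 2, 8: 2, 9: 2}


def generate_cohort(
    n_subjects: int = 3,
    n_cells_per_subject: int = 60,
    spec: LatentSpec | None = None,
    seed: int = 0,
    n_trials_per_session: int = 50,
    days: dict[int, int] | None = None,
    p_avoid: float = 0.7,
    p_iti_shuttle: float = 0.35,
    p_y_shuttle: float = 0.573,
    p_xshuttle_error: float = 0.5,
    tone_duration_s: float = 10.0,
) -> tuple[CohortDataset, GroundTruth]:
    """Generate a synthetic cohort with planted latent structure.

    Each session consists of ``n_trials_per_session`` trials: a 30 +/- 10 s
    inter-trial interval followed by a tone of at most ``tone_duration_s``.
    Avoid trials shuttle at a latency drawn uniformly from [3 s, 9 s] after
    tone start, upon which the tone turns off 1 s later; error trials hear
    the full tone and contain no shuttle.  Spontaneous ITI shuttles occur
    with probability ``p_iti_shuttle`` per interval.  Task-1 shuttles cross
    the arena's x midline; task-2 avoidance shuttles cross the y midline
    only (probability ``p_y_shuttle``) or both midlines.  A fraction
    ``p_xshuttle_error`` of task-2 error trials contains an incorrect X
    shuttle (the action learned in task 1, which no longer terminates the
    tone): these trials carry motion and the behaviour-gated tone drop
    while the tone stays on, recorded in the ``shuttle_time`` column.

    Parameters
    ----------
    days
        Mapping day number -> task number; defaults to two sessions per
        task ({3: 1, 4: 1, 6: 2, 7: 2}).
    seed
        Seeds all randomness; identical seeds give bit-identical cohorts.

    Returns
    -------
    (CohortDataset, GroundTruth)
    """
    spec = spec if spec is not None else LatentSpec()
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    if n_cells_per_subject <= spec.n_latents:
        raise ValueError(
            f"n_cells_per_subject ({n_cells_per_subject}) must exceed the "
            f"latent count ({spec.n_latents}) for full-column-rank loadings"
        )
    days = days if days is not None else _default_days()
    rng = np.random.default_rng(seed)

    subjects: list[SubjectData] = []
    all_loadings: list[np.ndarray] = []
    all_latents: list[np.ndarray] = []

    for s in range(n_subjects):
        subject_id = f"S{s + 1:02d}"
        trial_rows: list[dict] = []
        session_bounds: dict[int, tuple[int, int]] = {}
        latent_chunks: list[np.ndarray] = []
        tone_chunks: list[np.ndarray] = []
        track_chunks: list[np.ndarray] = []
        t_offset = 0  # samples

        for day, task in sorted(days.items()):
            lat, tone, track, rows, n_samp = _generate_session(
                spec,
                rng,
                task=task,
                n_trials=n_trials_per_session,
                p_avoid=p_avoid,
                p_iti_shuttle=p_iti_shuttle,
                p_y_shuttle=p_y_shuttle,
                p_xshuttle_error=p_xshuttle_error,
                tone_duration_s=tone_duration_s,
                t_offset_s=t_offset * DT,
            )
            for r in rows:
                r.update(subject=subject_id, day=day, task=task)
            trial_rows.extend(rows)
            session_bounds[day] = (t_offset, t_offset + n_samp)
            latent_chunks.append(lat)
            tone_chunks.append(tone)
            track_chunks.append(track)
            t_offset += n_samp

        latents = np.concatenate(latent_chunks, axis=1)
        tone = np.concatenate(tone_chunks)
        tracking = np.concatenate(track_chunks, axis=1)

        # dense Gaussian loadings, column-orthonormalised: every cell mixes
        # every latent (mixed selectivity) and the columns have full rank
        raw = rng.standard_normal((n_cells_per_subject, spec.n_latents))
        loadings, r_ = np.linalg.qr(raw)
        loadings = loadings * np.sign(np.diag(r_))

        traces = loadings @ latents
        if spec.noise_sigma > 0:
            traces = traces + spec.noise_sigma * rng.standard_normal(traces.shape)

        trials = pd.DataFrame(trial_rows)
        trials["trial_id"] = np.arange(len(trials))
        trials = trials[
            [
                "subject",
                "day",
                "task",
                "trial_id",
                "type",
                "tone_on",
                "tone_off",
                "align_time",
                "shuttle_time",
                "shuttle_class",
            ]
        ]
        subjects.append(
            SubjectData(
                subject=subject_id,
                traces=traces,
                tracking=tracking,
                point_labels=POINT_LABELS,
                tone=tone,
                trials=trials,
                session_bounds=session_bounds,
            )
        )
        all_loadings.append(loadings)
        all_latents.append(latents)

    truth = GroundTruth(
        loadings=all_loadings,
        latent_labels=spec.labels,
        latents=all_latents,
        spec=spec,
        seed=seed,
        condition_timecourses={
            c: generate_latent_timecourses(spec, c) for c in CONDITIONS
        },
    )
    return CohortDataset(subjects=subjects), truth


def _generate_session(
    spec: LatentSpec,
    rng: np.random.Generator,
    task: int,
    n_trials: int,
    p_avoid: float,
    p_iti_shuttle: float,
    p_y_shuttle: float,
    p_xshuttle_error: float,
    tone_duration_s: float,
    t_offset_s: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[dict], int]:
    """Build one session: latents, tone, tracking and trial rows.

    All event times in the returned rows are absolute (offset by
    ``t_offset_s``) so the whole subject lives on one clock.
    """
    # --- lay out events in session-relative seconds -----------------------
    events: list[dict] = []  # shuttle events (avoid + ITI), for tracking/latents
    rows: list[dict] = []
    t = 0.0
    for _ in range(n_trials):
        iti = rng.uniform(20.0, 40.0)
        # spontaneous ITI shuttle, kept clear of the surrounding tones
        if rng.random() < p_iti_shuttle and iti > 18.0:
            iti_shuttle = t + rng.uniform(6.0, iti - 6.0)
            cls = "X" if task == 1 else "Y"
            events.append({"time": iti_shuttle, "class": cls, "kind": "iti"})
            rows.append(
                {
                    "type": "iti_shuttle",
                    "tone_on": np.nan,
                    "tone_off": np.nan,
                    "align_time": t_offset_s + iti_shuttle,
                    "shuttle_time": t_offset_s + iti_shuttle,
                    "shuttle_class": cls,
                }
            )
        tone_on = t + iti
        if rng.random() < p_avoid:
            latency = rng.uniform(3.0, 9.0)
            shuttle = tone_on + latency
            tone_off = shuttle + 1.0
            if task == 1:
                cls = "X"
            else:
                cls = "Y" if rng.random() < p_y_shuttle else "XY"
            events.append({"time": shuttle, "class": cls, "kind": "avoid"})
            rows.append(
                {
                    "type": "avoid",
                    "tone_on": t_offset_s + tone_on,
                    "tone_off": t_offset_s + tone_off,
                    "align_time": t_offset_s + shuttle,
                    "shuttle_time": t_offset_s + shuttle,
                    "shuttle_class": cls,
                }
            )
        else:
            tone_off = tone_on + tone_duration_s
            # in task 2, errors may contain the incorrect (task-1) X shuttle:
            # real motion and a behaviour-gated tone drop, but the tone stays on
            shuttle_time = np.nan
            cls = ""
            if task == 2 and rng.random() < p_xshuttle_error:
                shuttle = tone_on + rng.uniform(3.0, 9.0)
                shuttle_time = t_offset_s + shuttle
                cls = "X"
                events.append({"time": shuttle, "class": cls, "kind": "error"})
            rows.append(
                {
                    "type": "error",
                    "tone_on": t_offset_s + tone_on,
                    "tone_off": t_offset_s + tone_off,
                    "align_time": np.nan,
                    "shuttle_time": shuttle_time,
                    "shuttle_class": cls,
                }
            )
        t = tone_on + tone_duration_s + 2.0  # post-trial margin
    n_samp = int(np.ceil((t + 5.0) * FS))
    times = np.arange(n_samp) * DT

    # --- latents ----------------------------------------------------------
    latents = np.zeros((spec.n_latents, n_samp))
    i_av = spec.n_motion
    i_av2 = i_av + spec.n_avoid_shared
    i_tone = i_av2 + spec.n_avoid_task2
    for ev in events:
        latents[: spec.n_motion] += _motion_shapes(spec, times, ev["time"])
        if ev["kind"] == "avoid":
            for j in range(spec.n_avoid_shared):
                latents[i_av + j] += _ramp(times, ev["time"], spec.ramp_onset_s, 1.0)
            if task == 2:
                for j in range(spec.n_avoid_task2):
                    latents[i_av2 + j] += _ramp(
                        times, ev["time"], spec.ramp_onset_s / 2.0, 1.5
                    )
    if spec.motion_background_sigma > 0 and spec.n_motion:
        bg = gaussian_filter1d(
            rng.standard_normal((spec.n_motion, n_samp)),
            sigma=spec.motion_background_smooth_steps,
            axis=1,
        )
        sd = bg.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        latents[: spec.n_motion] += spec.motion_background_sigma * bg / sd
    tone = np.zeros(n_samp)
    for r in rows:
        if r["type"] == "iti_shuttle":
            continue
        on = r["tone_on"] - t_offset_s
        off = r["tone_off"] - t_offset_s
        tone[(times >= on) & (times < off)] = 1.0
        shuttle = (
            r["shuttle_time"] - t_offset_s if np.isfinite(r["shuttle_time"]) else None
        )
        for j in range(spec.n_tone):
            latents[i_tone + j] += _tone_shape(spec, times, on, off, shuttle)
    latents *= spec.effect_size

    # --- tracking ---------------------------------------------------------
    tracking = _generate_tracking(rng, times, events)
    return latents, tone, tracking, rows, n_samp


def _generate_tracking(
    rng: np.random.Generator, times: np.ndarray, events: list[dict]
) -> np.ndarray:
    """Five-point tracking: a centroid path plus per-point rigid offsets.

    The centroid sits near the middle of its current arena quadrant and
    translates across the relevant midline(s) with a smoothstep profile of
    duration 1.4 s starting at each shuttle event time, so that the speed
    of the animal peaks shortly after shuttle start and the midline is
    crossed near the middle of the movement.
    """
    lo, hi = 50.0, 150.0
    x_side, y_side = 0, 0
    x = np.full(times.size, lo)
    y = np.full(times.size, lo)
    for ev in sorted(events, key=lambda e: e["time"]):
        u = _smoothstep((times - ev["time"]) / _SMOOTHSTEP_DUR)
        if "X" in ev["class"]:
            start = hi if x_side else lo
            end = lo if x_side else hi
            x = np.where(times < ev["time"], x, start + (end - start) * u)
            x_side = 1 - x_side
        if "Y" in ev["class"]:
            start = hi if y_side else lo
            end = lo if y_side else hi
            y = np.where(times < ev["time"], y, start + (end - start) * u)
            y_side = 1 - y_side
    centroid = np.stack([x, y], axis=1)  # time x 2
    offsets = np.array(
        [[-3.0, -3.0], [3.0, -3.0], [0.0, 0.0], [0.0, -6.0], [0.0, 8.0]]
    )
    tracking = centroid[None, :, :] + offsets[:, None, :]
    tracking = tracking + 0.5 * rng.standard_normal(tracking.shape)
    return tracking


# ---------------------------------------------------------------------------
# movie generation


def generate_movie(
    cell_positions: list[tuple[float, float]],
    traces: np.ndarray,
    bleach_params: dict | None = None,
    frame_size: tuple[int, int] = (64, 64),
    baseline: float = 100.0,
    amplitude: float = 20.0,
    blob_sigma_px: float = 2.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> np.ndarray:
    """Render traces into a small fluorescence movie fixture.

    ``movie[t] = (baseline + sum_i amplitude * trace_i[t] * blob_i) * m(t) + a(t)``
    where the Gaussian blob ``blob_i`` is centred at ``cell_positions[i]``
    and ``m``/``a`` are multiplicative/additive bleaching trends from
    ``bleach_params`` (keys ``mode`` in {"multiplicative", "additive"},
    ``amplitude`` and ``tau_s`` of an exponential decay, ``fs``).

    Overlapping identical positions are allowed (used to exercise the
    duplicate-cell rule downstream).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    h, w = frame_size
    for (cy, cx) in cell_positions:
        if not (0 <= cy < h and 0 <= cx < w):
            raise ValueError(f"cell position ({cy}, {cx}) outside frame {frame_size}")
    if len(cell_positions) != traces.shape[0]:
        raise ValueError("one trace per cell position required")
    n_frames = traces.shape[1]

    yy, xx = np.mgrid[0:h, 0:w]
    blobs = np.stack(
        [
            np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2.0 * blob_sigma_px**2))
            for (cy, cx) in cell_positions
        ]
    )
    movie = baseline + amplitude * np.tensordot(traces.T, blobs, axes=(1, 0))

    if bleach_params:
        fs = bleach_params.get("fs", FS)
        t = np.arange(n_frames) / fs
        trend = bleach_params["amplitude"] * np.exp(-t / bleach_params["tau_s"])
        if bleach_params.get("mode", "multiplicative") == "multiplicative":
            movie = movie * (1.0 + trend)[:, None, None]
        else:
            movie = movie + trend[:, None, None]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        movie = movie + noise_sigma * rng.standard_normal(movie.shape)
    return movie
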