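"""End-to-end orchestration: cohort -> aligned tensors -> joint subspace ->
coding-dimension decomposition.

The functions here wire the per-module operations together the way the
full analysis runs: pseudoshuttle assignment, window extraction per
condition, a half/half split of trials into an alignment set and a
decoding set, subject alignment on the first half, and projection of the
second half into the joint subspace for decoding and decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .alignment import (
    CONDITION_ORDER,
    JointSubspace,
    build_joint_matrix,
    fit_joint_subspace,
)
from .decomposition import (
    CodingBasis,
    avoid_dimensions,
    build_coding_basis,
    motion_dimensions,
    tone_dimension,
)
from .events import (
    assign_pseudoshuttles,
    condition_averages,
    extract_windows,
    sample_iti_random_times,
)
from .synthetic import FS, CohortDataset, GroundTruth

#: Shuttle-aligned decoding window (s) and its slice within the
#: [-4 s, 4 s) ITI tensor.
DECODING_WINDOW = (-3.0, 1.0)
_ITI_DECODE_SLICE = slice(5, 25)

#: Tone-start window used for the tone-dimension data: 1 s baseline before
#: tone start followed by the first 5 s of the tone.
TONE_WINDOW = (-1.0, 5.0)
_BASELINE_STEPS = 5


@dataclass
class PreparedSubject:
    """Event-aligned tensors for one subject (cell space)."""

    trials: pd.DataFrame  # with pseudoshuttle align times assigned
    tensors: dict[str, np.ndarray]  # condition -> trials x cells x time
    ids: dict[str, np.ndarray]  # condition -> trial-table row labels
    tone_valid: dict[str, np.ndarray]  # tone windows: trials x time usable mask


def prepare_subject(
    subject, rng: np.random.Generator, n_iti_random: int = 40
) -> PreparedSubject:
    """Extract all per-condition trial tensors for one subject.

    Avoid/error conditions combine the tone-start (-1..3 s) and
    shuttle-start (-3..1 s) windows into 40-sample tensors; ITI shuttles
    use -4..4 s around shuttle start.  Error trials receive pseudoshuttle
    alignment points drawn from the avoid-latency distribution.  Random
    event-free ITI windows (the null class for ITI decoding) and
    tone-start windows (baseline + first 5 s) are extracted as well.
    """
    trials = assign_pseudoshuttles(subject.trials, rng)
    tensors: dict[str, np.ndarray] = {}
    ids: dict[str, np.ndarray] = {}
    tone_valid: dict[str, np.ndarray] = {}

    for task in (1, 2):
        for typ in ("avoid", "error"):
            rows = trials[(trials["task"] == task) & (trials["type"] == typ)]
            tone_t = extract_windows(subject.traces, rows, "tone-start", (-1.0, 3.0))
            shut_t = extract_windows(subject.traces, rows, "shuttle-start", (-3.0, 1.0))
            common, ia, ib = np.intersect1d(
                tone_t.trial_ids, shut_t.trial_ids, return_indices=True
            )
            key = f"{typ}-task{task}"
            tensors[key] = np.concatenate(
                [tone_t.data[ia], shut_t.data[ib]], axis=2
            )
            ids[key] = rows.index.to_numpy()[common]

        iti_rows = trials[(trials["task"] == task) & (trials["type"] == "iti_shuttle")]
        iti_t = extract_windows(subject.traces, iti_rows, "shuttle-start", (-4.0, 4.0))
        tensors[f"ITI-task{task}"] = iti_t.data
        ids[f"ITI-task{task}"] = iti_rows.index.to_numpy()[iti_t.trial_ids]

        # tone-dimension data: baseline (1 s before tone) + first 5 s of tone
        te_rows = trials[
            (trials["task"] == task) & (trials["type"].isin(["avoid", "error"]))
        ]
        tw = extract_windows(subject.traces, te_rows, "tone-start", TONE_WINDOW)
        key = f"tone-task{task}"
        tensors[key] = tw.data
        row_ids = te_rows.index.to_numpy()[tw.trial_ids]
        ids[key] = row_ids
        rel_t = tw.times  # -1.0 .. 4.8
        latency = (
            trials.loc[row_ids, "align_time"] - trials.loc[row_ids, "tone_on"]
        ).to_numpy()
        is_avoid = (trials.loc[row_ids, "type"] == "avoid").to_numpy()
        valid = np.ones((len(row_ids), rel_t.size), dtype=bool)
        valid &= rel_t[None, :] >= 0  # baseline steps are never tone samples
        # avoid trials contribute only pre-shuttle steps
        valid[is_avoid] &= rel_t[None, :] < latency[is_avoid, None]
        tone_valid[key] = valid

    # event-free random ITI periods
    times = sample_iti_random_times(subject, n_iti_random, rng)
    n_w = int(round((DECODING_WINDOW[1] - DECODING_WINDOW[0]) * subject.fs))
    chunks = []
    for t in times:
        start = int(round((t + DECODING_WINDOW[0]) * subject.fs))
        chunks.append(subject.traces[:, start : start + n_w])
    tensors["ITI-random"] = np.stack(chunks)
    ids["ITI-random"] = np.full(len(times), -1)

    return PreparedSubject(trials=trials, tensors=tensors, ids=ids, tone_valid=tone_valid)


@dataclass
class AlignedCohort:
    """Joint subspace fitted on the alignment half, decode half projected."""

    subspace: JointSubspace
    averages: list[dict[str, np.ndarray]]  # per subject, alignment half
    decode: dict[str, np.ndarray]  # condition -> pooled trials x k x time
    meta: dict[str, pd.DataFrame]  # condition -> trial metadata rows
    tone_valid: dict[str, np.ndarray]
    k: int


def align_cohort(
    cohort: CohortDataset,
    rng: np.random.Generator,
    k: int = 10,
    half_split: bool = True,
    n_iti_random: int = 40,
) -> AlignedCohort:
    """Fit the joint subspace and project held-out trials into it.

    With ``half_split`` (the default) each subject's trials are split
    50/50 per condition: the first half forms the condition averages the
    subspace is fitted on, the second half is projected for decoding, so
    the alignment cannot leak class information into the decoders.
    """
    prepared = [prepare_subject(s, rng, n_iti_random) for s in cohort.subjects]

    averages = []
    decode_parts: dict[str, list[np.ndarray]] = {}
    meta_parts: dict[str, list[pd.DataFrame]] = {}
    valid_parts: dict[str, list[np.ndarray]] = {}

    for prep in prepared:
        av_tensors = {}
        # the align/decode split is defined on trial-table rows so that the
        # avoid/error tensors and the tone-window tensors stay consistent
        align_rows: set = set()
        decode_rows: set = set()
        for cond in CONDITION_ORDER:
            row_ids = prep.ids[cond]
            n = len(row_ids)
            if half_split:
                perm = rng.permutation(n)
                a_sel = np.sort(perm[: n // 2])
                d_sel = np.sort(perm[n // 2 :])
            else:
                a_sel = d_sel = np.arange(n)
            align_rows.update(row_ids[a_sel])
            decode_rows.update(row_ids[d_sel])
            av_tensors[cond] = prep.tensors[cond][a_sel]
            decode_parts.setdefault(cond, []).append(prep.tensors[cond][d_sel])
            meta_parts.setdefault(cond, []).append(prep.trials.loc[row_ids[d_sel]])
        averages.append(condition_averages(av_tensors))

        for task in (1, 2):
            key = f"tone-task{task}"
            in_decode = np.isin(prep.ids[key], list(decode_rows))
            decode_parts.setdefault(key, []).append(prep.tensors[key][in_decode])
            meta_parts.setdefault(key, []).append(
                prep.trials.loc[prep.ids[key][in_decode]]
            )
            valid_parts.setdefault(key, []).append(prep.tone_valid[key][in_decode])
        decode_parts.setdefault("ITI-random", []).append(prep.tensors["ITI-random"])

    joint, slices = build_joint_matrix(averages)
    subspace = fit_joint_subspace(joint, slices, k=k)

    decode: dict[str, np.ndarray] = {}
    meta: dict[str, pd.DataFrame] = {}
    tone_valid: dict[str, np.ndarray] = {}
    for cond, parts in decode_parts.items():
        projected = [
            np.einsum("ck,tcx->tkx", subspace.projections[s], part)
            for s, part in enumerate(parts)
            if part.shape[0]
        ]
        decode[cond] = (
            np.concatenate(projected, axis=0)
            if projected
            else np.empty((0, k, parts[0].shape[2]))
        )
        if cond in meta_parts:
            meta[cond] = pd.concat(
                [m for m in meta_parts[cond] if len(m)], ignore_index=True
            )
    for key, parts in valid_parts.items():
        tone_valid[key] = np.concatenate([v for v in parts if len(v)], axis=0)
    return AlignedCohort(
        subspace=subspace,
        averages=averages,
        decode=decode,
        meta=meta,
        tone_valid=tone_valid,
        k=k,
    )


# ---------------------------------------------------------------------------
# decoding datasets


def avoid_error_dataset(
    ac: AlignedCohort, task: int | None = None
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Avoid-vs-error trials over the shuttle window (features x 20 steps)."""
    tasks = (1, 2) if task is None else (task,)
    xs, ys, metas = [], [], []
    for t in tasks:
        for typ, label in (("avoid", 1), ("error", 0)):
            data = ac.decode[f"{typ}-task{t}"][:, :, 20:]  # shuttle-start half
            xs.append(data)
            ys.append(np.full(data.shape[0], label))
            metas.append(ac.meta[f"{typ}-task{t}"])
    return (
        np.concatenate(xs, axis=0),
        np.concatenate(ys),
        pd.concat(metas, ignore_index=True),
    )


def iti_dataset(ac: AlignedCohort) -> tuple[np.ndarray, np.ndarray]:
    """ITI shuttles vs random event-free ITI periods ([-3, 1) s windows)."""
    shuttles = np.concatenate(
        [ac.decode["ITI-task1"], ac.decode["ITI-task2"]], axis=0
    )[:, :, _ITI_DECODE_SLICE]
    random_ = ac.decode["ITI-random"]
    X = np.concatenate([shuttles, random_], axis=0)
    y = np.concatenate([np.ones(len(shuttles)), np.zeros(len(random_))])
    return X, y


def iti_condition_average(ac: AlignedCohort) -> np.ndarray:
    """k x 80 matrix: task-1 and task-2 ITI shuttle averages, concatenated."""
    return np.concatenate(
        [ac.decode["ITI-task1"].mean(axis=0), ac.decode["ITI-task2"].mean(axis=0)],
        axis=1,
    )


def tone_dataset(
    ac: AlignedCohort,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tone-window data: (trials x k x 25 tone steps, valid mask, baseline)."""
    data = np.concatenate([ac.decode["tone-task1"], ac.decode["tone-task2"]], axis=0)
    valid = np.concatenate(
        [ac.tone_valid["tone-task1"], ac.tone_valid["tone-task2"]], axis=0
    )
    baseline = data[:, :, :_BASELINE_STEPS]
    tone = data[:, :, _BASELINE_STEPS:]
    return tone, valid[:, _BASELINE_STEPS:], baseline


def decompose_cohort(
    ac: AlignedCohort,
    rng: np.random.Generator,
    n_reps: int = 160,
    n_motion: int = 5,
    n_avoid: int = 5,
) -> tuple[CodingBasis, np.ndarray, np.ndarray]:
    """Run the full decomposition: motion PCA, avoid and tone decoders.

    Returns the canonical five-dimension coding basis plus the full motion
    (k x n_motion) and avoid (k x n_avoid) dimension sets used for the
    removal curves.
    """
    motion = motion_dimensions(iti_condition_average(ac), n_dims=n_motion)
    X, y, _ = avoid_error_dataset(ac)
    avoid = avoid_dimensions(
        X, y, motion[:, :2], n_dims=n_avoid, rng=rng, n_reps=n_reps
    )
    tone_X, tone_ok, baseline = tone_dataset(ac)
    prior = np.concatenate([motion[:, :2], avoid[:, :2]], axis=1)
    tone = tone_dimension(tone_X, tone_ok, baseline, prior, rng=rng, n_reps=n_reps)
    return build_coding_basis(motion, avoid, tone), motion, avoid


# ---------------------------------------------------------------------------
# ground-truth comparison


def planted_directions(
    truth: GroundTruth, subspace: JointSubspace
) -> list[dict[str, np.ndarray]]:
    """Per subject, each planted latent direction expressed in the subspace.

    The loading column of latent j, mapped through P_s and renormalised.
    Directions whose loading is poorly captured by the subspace keep their
    reduced norm before normalisation (the angle to the subspace itself is
    part of the recovery error).
    """
    out = []
    for s, loadings in enumerate(truth.loadings):
        p_s = subspace.projections[s]
        dirs = {}
        for j, label in enumerate(truth.latent_labels):
            v = p_s.T @ loadings[:, j]
            norm = np.linalg.norm(v)
            dirs[label] = v / norm if norm > 0 else v
        out.append(dirs)
    return out


def _vector_subspace_angle(v: np.ndarray, basis: np.ndarray) -> float:
    """Angle (deg) between a unit vector and the span of basis columns."""
    q, _ = np.linalg.qr(np.atleast_2d(basis.T).T)
    cos = np.linalg.norm(q.T @ v)
    return float(np.degrees(np.arccos(np.clip(cos, -1.0, 1.0))))


def recovery_angles(
    truth: GroundTruth, subspace: JointSubspace, basis: CodingBasis
) -> dict[str, float]:
    """Principal angle between each planted direction and its recovered family.

    Within a family (motion, avoid) the individual dimensions are only
    identified up to rotation — PCA mixes the two motion latents, and the
    iterative decoder mixes the shared and task-2 avoid latents — so each
    planted direction is compared against the span of its recovered
    family; the tone latent is compared against the tone vector itself.
    Angles are averaged over subjects.
    """
    dirs_per_subject = planted_directions(truth, subspace)
    motion_span = basis.vectors[:, :2]
    avoid_span = basis.vectors[:, 2:4]
    tone_vec = basis.vectors[:, 4:5]
    spans = {}
    for label in truth.latent_labels:
        if label.startswith("motion"):
            spans[label] = motion_span
        elif label.startswith("avoid"):
            spans[label] = avoid_span
        else:
            spans[label] = tone_vec
    angles: dict[str, list[float]] = {lab: [] for lab in truth.latent_labels}
    for dirs in dirs_per_subject:
        for label, v in dirs.items():
            angles[label].append(_vector_subspace_angle(v, spans[label]))
    return {lab: float(np.mean(v)) for lab, v in angles.items()}
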