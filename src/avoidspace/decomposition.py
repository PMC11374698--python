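"""Decomposition of the joint subspace into orthogonal coding dimensions.

The k-dimensional joint subspace is progressively decomposed into five
labelled coding dimensions plus a residual complement:

1. *Motion* dimensions: PCA of the ITI-shuttle condition averages (shuttle
   motion without tone or avoidance context); the first two are removed
   for the subsequent steps.
2. *Avoid* dimensions: iteratively, a time-independent avoid-vs-error
   decoder is trained on one randomly sampled timepoint per trial in the
   nullspace of everything found so far; its unit-normalised weight vector,
   mapped back to the joint subspace, is the next avoid dimension.
3. *Tone* dimension: same decoder construction for tone-on vs pre-tone
   baseline samples in the remaining nullspace.

Every dimension is orthogonal to all previously found ones by
construction, so activity along, say, the tone dimension contains no
motion- or avoidance-related component.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import null_space

from .decoding import DecodingConfig, DecoderCurve, RepeatedResult, decode_timesteps, make_classifier, rank_ci, repeat_with_ci

CODING_LABELS = ("motion-1", "motion-2", "avoid-1", "avoid-2", "tone")


@dataclass
class CodingBasis:
    """Ordered orthonormal coding dimensions in the joint subspace."""

    vectors: np.ndarray  # k x n_dims, columns ordered as `labels`
    labels: tuple[str, ...] = CODING_LABELS
    residual: np.ndarray = field(default=None)  # k x (k - n_dims)

    def __post_init__(self) -> None:
        if self.residual is None:
            self.residual = nullspace_basis(self.vectors)
        full = np.concatenate([self.vectors, self.residual], axis=1)
        gram_err = np.abs(full.T @ full - np.eye(full.shape[1])).max()
        if gram_err > 1e-8:
            raise ValueError(f"coding basis not orthonormal (err={gram_err:.2e})")

    @property
    def k(self) -> int:
        return self.vectors.shape[0]

    def full_basis(self) -> np.ndarray:
        return np.concatenate([self.vectors, self.residual], axis=1)


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|.| entry of each column > 0."""
    flip = np.sign(
        vectors[np.argmax(np.abs(vectors), axis=0), np.arange(vectors.shape[1])]
    )
    flip[flip == 0] = 1.0
    return vectors * flip


def nullspace_basis(dims: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the orthogonal complement of ``dims``' columns."""
    basis = null_space(np.atleast_2d(np.asarray(dims, dtype=float)).T)
    return _fix_signs(basis)


def nullspace_project(data: np.ndarray, dims: np.ndarray, axis: int = 0) -> np.ndarray:
    """Remove the component of ``data`` along each column of ``dims``.

    ``dims`` must have orthonormal columns; ``axis`` is the feature axis of
    ``data``.  The operation is an orthogonal projection: idempotent and
    norm non-increasing, and the output has zero inner product with every
    removed dimension.
    """
    dims = np.atleast_2d(np.asarray(dims, dtype=float))
    if dims.ndim != 2:
        raise ValueError("dims must be a k x r matrix")
    err = np.abs(dims.T @ dims - np.eye(dims.shape[1])).max()
    if err > 1e-8:
        raise ValueError(f"removed dimensions not orthonormal (err={err:.2e})")
    x = np.moveaxis(np.asarray(data, dtype=float), axis, 0)
    out = x - np.tensordot(dims @ dims.T, x, axes=(1, 0))
    return np.moveaxis(out, 0, axis)


def motion_dimensions(
    iti_averages: np.ndarray, n_dims: int = 5
) -> np.ndarray:
    """Principal directions of ITI-shuttle dynamics in the joint subspace.

    ``iti_averages`` is k x time (task-1 and task-2 ITI shuttle averages
    over [-4 s, 4 s], concatenated along time).  Rows are centred over
    time before PCA.  Returns k x n_dims ordered unit vectors; if the
    averages have lower rank, the available directions are returned with a
    warning.
    """
    x = np.asarray(iti_averages, dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    u, svals, _ = np.linalg.svd(x, full_matrices=False)
    total = float(np.sum(svals**2))
    if total == 0:
        warnings.warn("ITI averages carry no variance; no motion dimensions")
        return np.empty((x.shape[0], 0))
    rank = int(np.sum(svals > svals[0] * 1e-10))
    if rank < n_dims:
        warnings.warn(
            f"ITI averages have rank {rank} < {n_dims}; returning {rank} "
            "motion dimensions"
        )
        n_dims = rank
    return _fix_signs(u[:, :n_dims])


def _time_independent_decoder_direction(
    coords: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    valid_mask: np.ndarray | None,
    n_reps: int,
    C: float,
) -> np.ndarray:
    """Averaged unit weight vector of a time-independent decoder.

    Per repetition, the classes are balanced by subsampling to the size of
    the smaller class, one timepoint is drawn uniformly per trial (from
    its valid steps), a linear SVM is fitted on the resulting trials x
    features matrix, and the unit-normalised weight vector is recorded.
    The repetition vectors are combined into one axis estimate as the
    principal eigenvector of their summed outer products — the average
    that is invariant to the arbitrary sign of each fitted hyperplane.
    """
    n_trials, n_feat, n_time = coords.shape
    if valid_mask is None:
        valid_mask = np.ones((n_trials, n_time), dtype=bool)
    usable = valid_mask.any(axis=1)
    coords, y, valid_mask = coords[usable], y[usable], valid_mask[usable]
    classes = np.unique(y)
    n_min = min(np.sum(y == c) for c in classes)
    vectors = []
    for _ in range(n_reps):
        sel = np.concatenate(
            [
                rng.choice(np.flatnonzero(y == c), size=n_min, replace=False)
                for c in classes
            ]
        )
        mask_sel = valid_mask[sel]
        if mask_sel.all():
            cols = rng.integers(0, n_time, size=sel.size)
        else:
            cols = np.array([rng.choice(np.flatnonzero(m)) for m in mask_sel])
        x = coords[sel, :, :][np.arange(sel.size), :, cols]
        clf = make_classifier(C, seed=int(rng.integers(2**31)))
        clf.fit(x, y[sel])
        w = clf.coef_.ravel()
        norm = np.linalg.norm(w)
        if norm == 0:
            raise ValueError("degenerate decoder: zero weight vector")
        vectors.append(w / norm)
    vecs = np.stack(vectors)
    _, eigvecs = np.linalg.eigh(vecs.T @ vecs)
    mean_vec = eigvecs[:, -1]
    # orient along the majority of repetition vectors
    if np.sum(np.sign(vecs @ mean_vec)) < 0:
        mean_vec = -mean_vec
    return mean_vec / np.linalg.norm(mean_vec)


def avoid_dimensions(
    trial_data: np.ndarray,
    y: np.ndarray,
    motion_dims: np.ndarray,
    n_dims: int = 5,
    rng: np.random.Generator | None = None,
    n_reps: int = 80,
    C: float = 1.0,
) -> np.ndarray:
    """Iterative avoid-coding dimensions orthogonal to the motion dimensions.

    ``trial_data`` is trials x k x time (avoid and error trials over the
    [-3 s, 1 s] shuttle-start window, in joint-subspace coordinates), ``y``
    the binary avoid/error labels and ``motion_dims`` the k x 2 motion
    dimensions whose nullspace the search starts in.  Each iteration trains
    a time-independent avoid/error decoder on one random timepoint per
    trial, unit-normalises its weight vector, maps it back from nullspace
    coordinates to the joint subspace, and shrinks the nullspace.

    Returns k x n_dims unit vectors, mutually orthogonal and orthogonal to
    ``motion_dims``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    prior = np.atleast_2d(np.asarray(motion_dims, dtype=float))
    found = []
    for _ in range(n_dims):
        basis = nullspace_basis(prior)  # k x m
        coords = np.einsum("km,tkx->tmx", basis, trial_data)
        w = _time_independent_decoder_direction(coords, y, rng, None, n_reps, C)
        v = basis @ w  # back to the joint subspace
        found.append(v)
        prior = np.concatenate([prior, v[:, None]], axis=1)
    return np.stack(found, axis=1)


def tone_dimension(
    tone_data: np.ndarray,
    tone_valid: np.ndarray,
    baseline_data: np.ndarray,
    prior_dims: np.ndarray,
    rng: np.random.Generator | None = None,
    n_reps: int = 80,
    C: float = 1.0,
) -> np.ndarray:
    """Tone-coding dimension in the nullspace of motion and avoid dimensions.

    ``tone_data`` holds trials x k x time from the first 5 s of avoid and
    error trials; ``tone_valid`` marks, per trial, which steps are usable
    (pre-shuttle, tone on).  ``baseline_data`` holds trials x k x time from
    the 1 s before tone start.  A time-independent tone-vs-baseline
    decoder (one sampled timepoint per trial and class) defines the
    direction, exactly as for the avoid dimensions.
    """
    rng = rng if rng is not None else np.random.default_rng()
    prior = np.atleast_2d(np.asarray(prior_dims, dtype=float))
    if not tone_valid.any(axis=1).any():
        raise ValueError("no pre-shuttle tone samples available")
    basis = nullspace_basis(prior)
    tone_c = np.einsum("km,tkx->tmx", basis, tone_data)
    base_c = np.einsum("km,tkx->tmx", basis, baseline_data)
    # the two windows differ in length; zero-pad the shorter and mask it out
    n_time = max(tone_c.shape[2], base_c.shape[2])
    base_valid = np.zeros((base_c.shape[0], n_time), dtype=bool)
    base_valid[:, : base_c.shape[2]] = True
    tone_valid_p = np.zeros((tone_c.shape[0], n_time), dtype=bool)
    tone_valid_p[:, : tone_c.shape[2]] = tone_valid
    pad = lambda a: np.pad(a, ((0, 0), (0, 0), (0, n_time - a.shape[2])))
    coords = np.concatenate([pad(tone_c), pad(base_c)], axis=0)
    valid = np.concatenate([tone_valid_p, base_valid], axis=0)
    y = np.concatenate([np.ones(tone_c.shape[0]), np.zeros(base_c.shape[0])])
    w = _time_independent_decoder_direction(coords, y, rng, valid, n_reps, C)
    return basis @ w


def build_coding_basis(
    motion: np.ndarray, avoid: np.ndarray, tone: np.ndarray
) -> CodingBasis:
    """Assemble the canonical basis: motion-1/2, avoid-1/2, tone + residual."""
    vectors = np.concatenate(
        [motion[:, :2], avoid[:, :2], tone.reshape(-1, 1)], axis=1
    )
    return CodingBasis(vectors=vectors)


def remove_and_evaluate(
    trial_data: np.ndarray,
    y: np.ndarray,
    ordered_dims: np.ndarray,
    cfg: DecodingConfig,
    seed: int = 0,
    max_removed: int | None = None,
    n_rep: int = 10,
    valid_mask: np.ndarray | None = None,
    setting: str = "",
) -> "RemovalCurve":
    """Decoding accuracy after progressive nullspace removal of dimensions.

    For r = 0..R, the trial data are projected into the nullspace of the
    first r columns of ``ordered_dims`` and the per-timestep decoding
    analysis is repeated ``n_rep`` times; the time-averaged accuracy, its
    rank CI, and the drop relative to r = 0 are reported.
    """
    ordered_dims = np.atleast_2d(np.asarray(ordered_dims, dtype=float))
    k = trial_data.shape[1]
    R = ordered_dims.shape[1] if max_removed is None else max_removed
    if R > k:
        raise ValueError(f"cannot remove {R} of {k} dimensions")
    means, los, his = [], [], []
    for r in range(R + 1):
        data_r = (
            trial_data
            if r == 0
            else nullspace_project(trial_data, ordered_dims[:, :r], axis=1)
        )
        result = repeat_with_ci(
            lambda rng: np.nanmean(
                decode_timesteps(data_r, y, cfg, rng, valid_mask=valid_mask)
            ),
            n_rep=n_rep,
            seed=seed + r,
        )
        lo, hi = rank_ci(result.values.ravel())
        means.append(float(result.values.mean()))
        los.append(float(lo))
        his.append(float(hi))
    means = np.array(means)
    return RemovalCurve(
        n_removed=np.arange(R + 1),
        accuracy=means,
        ci_low=np.array(los),
        ci_high=np.array(his),
        drop=means[0] - means,
        setting=setting,
    )


@dataclass
class RemovalCurve:
    n_removed: np.ndarray
    accuracy: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    drop: np.ndarray
    setting: str = ""


def evaluate_decoder_by_day(
    trial_data: np.ndarray,
    y: np.ndarray,
    days: np.ndarray,
    cfg: DecodingConfig,
    seed: int = 0,
    n_rep: int = 10,
    n_per_class_split: int = 150,
    window_steps: slice = slice(None),
) -> "PerDayResult":
    """Train decoders on all days, evaluate accuracy separately per day.

    Uses a single train/test split (``n_per_class_split`` trials per class
    each) instead of cross-validation.  Per repetition and time step a
    decoder is fitted on the training half; test accuracy is computed per
    day and averaged over ``window_steps``.  A day is flagged 'above
    chance' when 0.5 lies outside its rank CI.
    """
    rng_master = np.random.default_rng(seed)
    trial_data = np.asarray(trial_data, dtype=float)
    y = np.asarray(y)
    days = np.asarray(days)
    uniq_days = np.unique(days)
    classes = np.unique(y)
    step_idx = np.arange(trial_data.shape[2])[window_steps]

    accs = np.full((n_rep, uniq_days.size), np.nan)
    for rep in range(n_rep):
        rng = np.random.default_rng(int(rng_master.integers(2**31)))
        train_idx, test_idx = [], []
        for c in classes:
            members = rng.permutation(np.flatnonzero(y == c))
            if members.size < 2 * n_per_class_split:
                raise ValueError(
                    f"class {c!r}: need {2 * n_per_class_split} trials for the "
                    f"split, have {members.size}"
                )
            train_idx.append(members[:n_per_class_split])
            test_idx.append(members[n_per_class_split : 2 * n_per_class_split])
        train_idx = np.concatenate(train_idx)
        test_idx = np.concatenate(test_idx)
        day_acc = {d: [] for d in uniq_days}
        for t in step_idx:
            clf = make_classifier(cfg.C, seed=int(rng.integers(2**31)))
            clf.fit(trial_data[train_idx, :, t], y[train_idx])
            pred = clf.predict(trial_data[test_idx, :, t])
            correct = pred == y[test_idx]
            for d in uniq_days:
                sel = days[test_idx] == d
                if sel.any():
                    day_acc[d].append(correct[sel].mean())
        for j, d in enumerate(uniq_days):
            if day_acc[d]:
                accs[rep, j] = np.mean(day_acc[d])

    mean = np.nanmean(accs, axis=0)
    lo = np.empty(uniq_days.size)
    hi = np.empty(uniq_days.size)
    for j in range(uniq_days.size):
        lo[j], hi[j] = rank_ci(accs[~np.isnan(accs[:, j]), j])
    return PerDayResult(
        days=uniq_days,
        accuracy=mean,
        ci_low=lo,
        ci_high=hi,
        above_chance=lo > 0.5,
    )


@dataclass
class PerDayResult:
    days: np.ndarray
    accuracy: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    above_chance: np.ndarray
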