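"""Linear decoding machinery: per-timestep SVMs, repetitions, bootstrap CIs.

All decoders are linear max-margin classifiers (hinge loss) with box
constraint C = 1 and five-fold stratified cross-validation; classes are
balanced by subsampling before fitting.  Analyses are repeated with
independently drawn trial samples and summarised by the sorted-rank 95%
bootstrap confidence interval (3rd and 78th of 80 sorted values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

logger = logging.getLogger(__name__)


@dataclass
class DecodingConfig:
    """Settings shared by all decoding analyses."""

    C: float = 1.0  # SVM box constraint
    n_folds: int = 5
    n_per_class: int = 300
    n_repetitions: int = 80
    window: tuple[float, float] = (-3.0, 1.0)
    fs: float = 5.0
    standardize: bool = False  # no per-feature scaling by default

    def __post_init__(self) -> None:
        if self.n_per_class <= self.n_folds:
            raise ValueError("n_per_class must exceed the number of folds")


@dataclass
class DecoderCurve:
    """Per-timestep decoding accuracies over analysis repetitions."""

    times: np.ndarray  # seconds relative to the alignment event
    accuracies: np.ndarray  # repetitions x time, NaN where a step was skipped
    setting: str = ""
    config: DecodingConfig | None = None

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.accuracies, axis=0)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.empty(self.accuracies.shape[1])
        hi = np.empty(self.accuracies.shape[1])
        for t in range(self.accuracies.shape[1]):
            vals = self.accuracies[:, t]
            lo[t], hi[t] = rank_ci(vals[np.isfinite(vals)])
        return lo, hi

    @property
    def time_averaged(self) -> np.ndarray:
        """Per-repetition accuracy averaged over the time axis."""
        return np.nanmean(self.accuracies, axis=1)

    def time_averaged_ci(self) -> tuple[float, float, float]:
        vals = self.time_averaged
        lo, hi = rank_ci(vals)
        return float(np.mean(vals)), float(lo), float(hi)


def rank_ci(values: np.ndarray) -> tuple[float, float]:
    """Sorted-rank 95% bootstrap CI.

    For 80 repetitions the borders are the 3rd and 78th sorted values
    (covering 76/80 = 95% of the values); for other n the analogous
    floor-based ranks ``floor(0.025 n) + 1`` and ``n - floor(0.025 n)``
    (1-based) are used.
    """
    values = np.sort(np.asarray(values, dtype=float))
    n = values.size
    if n < 4:
        raise ValueError("rank CI requires at least 4 values")
    lo_rank = int(np.floor(0.025 * n)) + 1
    hi_rank = n - int(np.floor(0.025 * n))
    return float(values[lo_rank - 1]), float(values[hi_rank - 1])


def significantly_different(
    ci_a: tuple[float, float], ci_b: tuple[float, float]
) -> bool:
    """Significance by nonoverlapping 95% CIs."""
    return ci_a[1] < ci_b[0] or ci_b[1] < ci_a[0]


def make_classifier(C: float = 1.0, seed: int | None = None) -> SVC:
    """Linear max-margin classifier (hinge loss) with box constraint C."""
    return SVC(kernel="linear", C=C, random_state=seed)


def balance_classes(
    y: np.ndarray, n_per_class: int, rng: np.random.Generator
) -> np.ndarray:
    """Indices of a balanced subsample: n_per_class per class, no replacement."""
    y = np.asarray(y)
    classes = np.unique(y)
    idx = []
    for c in classes:
        members = np.flatnonzero(y == c)
        if members.size < n_per_class:
            raise ValueError(
                f"class {c!r} has {members.size} trials, fewer than the "
                f"requested {n_per_class}; use a smaller n_per_class"
            )
        idx.append(rng.choice(members, size=n_per_class, replace=False))
    return np.sort(np.concatenate(idx))


def _cv_accuracy(
    x: np.ndarray, y: np.ndarray, cfg: DecodingConfig, seed: int
) -> float:
    if cfg.standardize:
        sd = x.std(axis=0)
        x = (x - x.mean(axis=0)) / np.where(sd > 0, sd, 1.0)
    clf = make_classifier(cfg.C, seed)
    cv = StratifiedKFold(n_splits=cfg.n_folds, shuffle=True, random_state=seed)
    return float(np.mean(cross_val_score(clf, x, y, cv=cv)))


def decode_timesteps(
    X: np.ndarray,
    y: np.ndarray,
    cfg: DecodingConfig,
    rng: np.random.Generator,
    valid_mask: np.ndarray | None = None,
    balance: bool = True,
) -> np.ndarray:
    """One repetition of per-timestep decoding; returns accuracy per step.

    ``X`` is trials x features x time.  ``valid_mask`` (trials x time)
    marks samples that may be used at each step — e.g. post-shuttle steps
    where the tone has already turned off are excluded from avoid trials so
    the decoder cannot exploit tone-off information.  Steps where either
    class has fewer valid trials than folds return NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.unique(y).size != 2:
        raise ValueError("binary labels required")
    if balance:
        idx = balance_classes(y, cfg.n_per_class, rng)
        X, y = X[idx], y[idx]
        valid_mask = valid_mask[idx] if valid_mask is not None else None
    n_time = X.shape[2]
    acc = np.full(n_time, np.nan)
    for t in range(n_time):
        if valid_mask is not None:
            keep = valid_mask[:, t]
            xt, yt = X[keep, :, t], y[keep]
        else:
            xt, yt = X[:, :, t], y
        counts = np.bincount(pd.factorize(yt)[0], minlength=2)
        if counts.min() < cfg.n_folds:
            logger.info("time step %d skipped: too few valid trials", t)
            continue
        acc[t] = _cv_accuracy(xt, yt, cfg, seed=int(rng.integers(2**31)))
    return acc


def train_timestep_decoders(
    X: np.ndarray,
    y: np.ndarray,
    cfg: DecodingConfig,
    seed: int = 0,
    valid_mask: np.ndarray | None = None,
    setting: str = "",
) -> DecoderCurve:
    """Per-timestep decoders over ``cfg.n_repetitions`` trial samples."""
    rng = np.random.default_rng(seed)
    accs = np.stack(
        [
            decode_timesteps(X, y, cfg, rng, valid_mask=valid_mask)
            for _ in range(cfg.n_repetitions)
        ]
    )
    n_time = X.shape[2]
    times = cfg.window[0] + np.arange(n_time) / cfg.fs
    return DecoderCurve(times=times, accuracies=accs, setting=setting, config=cfg)


def repeat_with_ci(
    analysis: Callable[[np.random.Generator], np.ndarray],
    n_rep: int = 80,
    seed: int = 0,
) -> "RepeatedResult":
    """Run a seeded analysis ``n_rep`` times; mean and rank CI per element."""
    if n_rep < 4:
        raise ValueError("n_rep must be at least 4 for the rank CI")
    rng = np.random.default_rng(seed)
    values = np.stack(
        [np.asarray(analysis(np.random.default_rng(int(rng.integers(2**31)))), dtype=float)
         for _ in range(n_rep)]
    )
    return RepeatedResult(values=values)


@dataclass
class RepeatedResult:
    values: np.ndarray  # repetitions x ...

    @property
    def mean(self) -> np.ndarray:
        return np.nanmean(self.values, axis=0)

    @property
    def ci(self) -> tuple[np.ndarray, np.ndarray]:
        flat = self.values.reshape(self.values.shape[0], -1)
        lo = np.empty(flat.shape[1])
        hi = np.empty(flat.shape[1])
        for j in range(flat.shape[1]):
            lo[j], hi[j] = rank_ci(flat[:, j])
        shape = self.values.shape[1:]
        return lo.reshape(shape), hi.reshape(shape)


def select_iti_shuttles(
    shuttles: pd.DataFrame, n_per_session: int = 10, speed_column: str = "mean_speed"
) -> pd.DataFrame:
    """The n fastest ITI shuttles per session (matched-motion control set).

    Faster shuttles carry more kinematic information; taking the ten
    fastest per session matches the video-decoder performance between the
    avoid and ITI settings.  Sessions with fewer shuttles contribute all
    of them (logged).
    """
    picked = []
    for (subject, day), group in shuttles.groupby(["subject", "day"], sort=True):
        if len(group) < n_per_session:
            logger.info(
                "session %s day %s: only %d shuttles available", subject, day, len(group)
            )
        picked.append(group.nlargest(min(n_per_session, len(group)), speed_column))
    return pd.concat(picked) if picked else shuttles.iloc[0:0]


def video_decoder_curve(
    speed_tensor: np.ndarray,
    y: np.ndarray,
    cfg: DecodingConfig,
    seed: int = 0,
    setting: str = "video",
) -> DecoderCurve:
    """Decoding from the five-dimensional tracking-point speed vector.

    The same per-timestep machinery applied to kinematic features; serves
    as the yardstick for how much decoding performance mere motion
    information can yield.
    """
    speed_tensor = np.asarray(speed_tensor, dtype=float)
    if speed_tensor.shape[1] != 5:
        raise ValueError("expected 5 per-point speed features")
    return train_timestep_decoders(speed_tensor, y, cfg, seed=seed, setting=setting)
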