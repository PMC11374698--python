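"""Descriptive population metrics on top of the coding-dimension basis.

Single-cell responsiveness and day-to-day overlap, variance explained per
coding dimension, projection correlations, mixed-selectivity weight
entropy, tone-drop dynamics, and task / shuttle-type decoding wrappers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .decoding import DecodingConfig, DecoderCurve, train_timestep_decoders
from .decomposition import CodingBasis
from .synthetic import FS

logger = logging.getLogger(__name__)

Z_THRESHOLD = 1.96  # two-tailed p < 0.05 under a normal assumption


def trial_responsiveness(
    traces: np.ndarray,
    trials: pd.DataFrame,
    day: int,
    fs: float = FS,
    baseline_s: float = 6.0,
    window_s: float = 3.0,
) -> pd.DataFrame:
    """Per-cell trial responsiveness for one day.

    For every avoid trial, activity in the 3 s after tone start and the
    3 s before shuttle start is z-scored against the per-trial baseline
    (the 6 s before tone start); a cell is responsive on that day iff its
    mean absolute z over trials and windows strictly exceeds 1.96.

    Returns a DataFrame with columns cell, day, mean_abs_z, responsive.
    Cells whose baseline has zero s.d. in any trial are skipped (logged).
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    day_trials = trials[(trials["day"] == day) & (trials["type"] == "avoid")]
    if day_trials.empty:
        raise ValueError(f"no avoid trials on day {day}")
    n_cells = traces.shape[0]
    abs_z_sums = np.zeros(n_cells)
    counts = np.zeros(n_cells)
    skipped = np.zeros(n_cells, dtype=bool)
    w = int(round(window_s * fs))
    b = int(round(baseline_s * fs))
    for _, row in day_trials.iterrows():
        i_tone = int(round(row["tone_on"] * fs))
        i_shut = int(round(row["align_time"] * fs))
        if i_tone - b < 0 or i_shut > traces.shape[1]:
            continue
        baseline = traces[:, i_tone - b : i_tone]
        mu, sd = baseline.mean(axis=1), baseline.std(axis=1)
        zero = sd == 0
        if zero.any():
            skipped |= zero
        sd = np.where(zero, 1.0, sd)
        windows = np.concatenate(
            [traces[:, i_tone : i_tone + w], traces[:, i_shut - w : i_shut]], axis=1
        )
        z = np.abs((windows - mu[:, None]) / sd[:, None])
        abs_z_sums += np.where(zero, 0.0, z.mean(axis=1))
        counts += ~zero
    if skipped.any():
        logger.info("%d cell(s) skipped: zero baseline s.d.", int(skipped.sum()))
    mean_abs_z = np.divide(
        abs_z_sums, counts, out=np.full(n_cells, np.nan), where=counts > 0
    )
    return pd.DataFrame(
        {
            "cell": np.arange(n_cells),
            "day": day,
            "mean_abs_z": mean_abs_z,
            "responsive": mean_abs_z > Z_THRESHOLD,
        }
    )


def overlap(set_i: set, set_j: set) -> float:
    """Overlap of two cell sets: |i ∩ j| / ((|i| + |j|) / 2)."""
    set_i, set_j = set(set_i), set(set_j)
    denom = (len(set_i) + len(set_j)) / 2.0
    if denom == 0:
        raise ValueError("overlap of two empty sets is undefined")
    return len(set_i & set_j) / denom


def variance_by_dimension(
    projection: np.ndarray, basis: CodingBasis
) -> pd.DataFrame:
    """Absolute and relative variance along each coding dimension.

    ``projection`` is a k x time trajectory in joint-subspace coordinates.
    Per labelled dimension the variance of its component time course is
    reported; the residual complement is pooled into one row.  Relative
    values are normalised by the total variance within the k-dimensional
    subspace, so they sum to 1 over the 5 dimensions plus residual.
    """
    x = np.asarray(projection, dtype=float)
    comp = basis.full_basis().T @ x  # (5 + residual) x time
    var = comp.var(axis=1)
    total = var.sum()
    if total <= 1e-15 * max(np.abs(x).max(), 1.0) ** 2:
        raise ValueError("projection carries no variance")
    n_coding = len(basis.labels)
    rows = [
        {"dimension": lab, "variance": var[i], "relative": var[i] / total}
        for i, lab in enumerate(basis.labels)
    ]
    rows.append(
        {
            "dimension": "residual",
            "variance": var[n_coding:].sum(),
            "relative": var[n_coding:].sum() / total,
        }
    )
    return pd.DataFrame(rows)


def projection_correlations(
    projections: dict[str, np.ndarray],
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Pearson correlation between pairs of coding-dimension projections.

    ``projections`` maps dimension label -> concatenated time course
    (avoid and error projections back to back).  Constant projections give
    a missing (NaN) coefficient.
    """
    if pairs is None:
        pairs = list(combinations(projections.keys(), 2))
    rows = []
    for a, b in pairs:
        xa, xb = np.asarray(projections[a]), np.asarray(projections[b])
        if xa.shape != xb.shape:
            raise ValueError(f"projections {a!r} and {b!r} differ in length")
        if xa.std() == 0 or xb.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(xa, xb)[0, 1])
        rows.append({"dim_a": a, "dim_b": b, "r": r})
    return pd.DataFrame(rows)


def weight_entropy(p_s: np.ndarray, basis: CodingBasis) -> pd.DataFrame:
    """Mixed-selectivity profile of each cell.

    A cell's signed weights onto the five coding dimensions are the rows
    of ``P_s @ B``; absolute weights are normalised to sum to 1 and their
    entropy (bits) measures selectivity: 0 for a cell loading on a single
    dimension, log2(5) ≈ 2.32 for perfectly mixed weights.
    """
    weights = np.asarray(p_s, dtype=float) @ basis.vectors  # cells x 5
    rows = []
    for c, w in enumerate(weights):
        total = np.abs(w).sum()
        if total == 0:
            logger.info("cell %d skipped: all-zero weights", c)
            continue
        p = np.abs(w) / total
        nz = p[p > 0]
        entropy = float(-(nz * np.log2(nz)).sum())
        rows.append(
            {
                "cell": c,
                **{f"w_{lab}": w[i] for i, lab in enumerate(basis.labels)},
                "entropy_bits": entropy,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tone-drop dynamics


def max_drop_point(x: np.ndarray) -> int:
    """Index of the time step before the maximal decrease between steps.

    With ``d[t] = x[t] - x[t+1]``, returns the (0-based) argmax of ``d``;
    monotonically non-decreasing input makes the drop undefined and only
    produces a warning.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples")
    decreases = x[:-1] - x[1:]
    if decreases.max() <= 0:
        warnings.warn("no decrease found; drop point is ill-defined", stacklevel=2)
    return int(np.argmax(decreases))


def drop_percentage(
    x_noshuttle: np.ndarray | float, x_shuttle: np.ndarray | float, lag_steps: int = 0
) -> float:
    """Relative drop of tone-dimension activity caused by the action.

    ``100 * (x_noshuttle - x_shuttle) / x_noshuttle`` at ``lag_steps``
    after the (matched) action onset; scalars are treated as already
    evaluated at the lag.
    """
    xn = np.atleast_1d(np.asarray(x_noshuttle, dtype=float))
    xs = np.atleast_1d(np.asarray(x_shuttle, dtype=float))
    i = lag_steps if xn.size > 1 else 0
    j = lag_steps if xs.size > 1 else 0
    if xn[i] == 0:
        raise ValueError("no-shuttle reference activity is zero at the lag")
    return float(100.0 * (xn[i] - xs[j]) / xn[i])


@dataclass
class ToneDropResult:
    tone_correlation: float
    drop_point: int
    drop_pct: float


def tone_drop_analysis(
    tone_projection: np.ndarray,
    tone_binary: np.ndarray,
    shuttle_aligned_mean: np.ndarray,
    noshuttle_aligned_mean: np.ndarray,
    lag_steps: int = 6,
) -> ToneDropResult:
    """Summary of tone-dimension dynamics around the avoidance action.

    Parameters
    ----------
    tone_projection, tone_binary
        Continuous tone-dimension projection and the binary tone on/off
        trace on the same clock (their Pearson correlation quantifies how
        faithfully the dimension tracks the stimulus).
    shuttle_aligned_mean, noshuttle_aligned_mean
        Trial-average tone-dimension activity aligned to (matched) action
        onset, with and without an actual shuttle.
    lag_steps
        Lag after action onset at which the drop percentage is evaluated
        (default 6 steps = 1.2 s at 5 Hz).
    """
    tone_projection = np.asarray(tone_projection, dtype=float)
    tone_binary = np.asarray(tone_binary, dtype=float)
    if tone_projection.std() == 0 or tone_binary.std() == 0:
        raise ValueError("constant signal: tone correlation undefined")
    r = float(np.corrcoef(tone_projection, tone_binary)[0, 1])
    return ToneDropResult(
        tone_correlation=r,
        drop_point=max_drop_point(shuttle_aligned_mean),
        drop_pct=drop_percentage(noshuttle_aligned_mean, shuttle_aligned_mean, lag_steps),
    )


def task_and_shuttletype_decoding(
    datasets: dict[str, tuple[np.ndarray, np.ndarray]],
    cfg: DecodingConfig,
    seed: int = 0,
    per_dimension: bool = False,
    dimension_labels: tuple[str, ...] | None = None,
) -> dict[str, DecoderCurve]:
    """Task (or shuttle-type) decoding per setting, optionally per dimension.

    ``datasets`` maps a setting label (e.g. 'avoid', 'error', 'ITI',
    'T1X-vs-T2XY') to a (trials x features x time, binary labels) pair in
    coding-space coordinates.  With ``per_dimension`` the decoding is
    additionally run on each single feature, keyed
    ``"<setting>/<dimension>"``.
    """
    curves: dict[str, DecoderCurve] = {}
    for i, (setting, (X, y)) in enumerate(datasets.items()):
        curves[setting] = train_timestep_decoders(
            X, y, cfg, seed=seed + i, setting=setting
        )
        if per_dimension:
            labels = dimension_labels or tuple(
                f"dim-{d + 1}" for d in range(X.shape[1])
            )
            for d, lab in enumerate(labels):
                curves[f"{setting}/{lab}"] = train_timestep_decoders(
                    X[:, d : d + 1, :], y, cfg, seed=seed + i, setting=f"{setting}/{lab}"
                )
    return curves
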