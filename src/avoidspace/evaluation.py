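"""High-level validation studies run on synthetic cohorts.

Each study generates (or receives) a cohort with planted structure, runs
the full analysis chain, and reduces the outcome to a few numbers: how
well the planted coding directions are recovered, how decoding accuracy
reacts to nullspace removal of coding dimensions, whether decoders are
calibrated at chance under null conditions, and how the tone dimension
behaves around the avoidance action.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import pipeline
from .decoding import DecodingConfig, decode_timesteps, rank_ci, repeat_with_ci, significantly_different
from .decomposition import remove_and_evaluate
from .events import extract_windows, sample_pseudoshuttle
from .metrics import drop_percentage, max_drop_point, variance_by_dimension
from .synthetic import LatentSpec, generate_cohort

#: Desk-scale decoding settings: 100 trials per class (the synthetic
#: cohorts pool ~150-400 trials per class across 3 subjects).
DESK_CFG = DecodingConfig(n_per_class=100, n_repetitions=10)


def _sub_seed(rng: np.random.Generator) -> int:
    return int(rng.integers(2**31))


def recovery_study(
    n_seeds: int = 20, base_seed: int = 0, n_reps: int = 160
) -> pd.DataFrame:
    """Planted-direction recovery angles (degrees) over independent cohorts.

    One row per cohort seed, one column per planted latent; each entry is
    the principal angle between the planted direction (expressed in the
    joint subspace) and the recovered coding family.
    """
    master = np.random.default_rng(base_seed)
    rows = []
    for _ in range(n_seeds):
        seed = _sub_seed(master)
        cohort, truth = generate_cohort(seed=seed)
        rng = np.random.default_rng(_sub_seed(master))
        ac = pipeline.align_cohort(cohort, rng)
        basis, _, _ = pipeline.decompose_cohort(ac, rng, n_reps=n_reps)
        rows.append(pipeline.recovery_angles(truth, ac.subspace, basis))
    return pd.DataFrame(rows)


@dataclass
class DissociationResult:
    """Removal-curve summary for one cohort (accuracies with rank CIs)."""

    av_baseline: tuple[float, float, float]  # (mean, ci_low, ci_high)
    av_motion_removed: tuple[float, float, float]
    av_avoid_removed: tuple[float, float, float]
    iti_baseline: tuple[float, float, float]
    iti_motion_removed: tuple[float, float, float]
    iti_avoid_removed: tuple[float, float, float]

    def motion_removal_dissociates(self) -> bool:
        """ITI decoding collapses toward chance, avoid decoding survives."""
        return (
            significantly_different(self.iti_baseline[1:], self.iti_motion_removed[1:])
            and self.iti_motion_removed[0] < 0.55
            and self.av_motion_removed[1] > 0.55
        )

    def avoid_removal_dissociates(self) -> bool:
        """Avoid decoding drops significantly, ITI decoding does not."""
        return significantly_different(
            self.av_baseline[1:], self.av_avoid_removed[1:]
        ) and not significantly_different(
            self.iti_baseline[1:], self.iti_avoid_removed[1:]
        )


def _curve_summary(rc) -> dict[int, tuple[float, float, float]]:
    return {
        int(r): (float(a), float(lo), float(hi))
        for r, a, lo, hi in zip(rc.n_removed, rc.accuracy, rc.ci_low, rc.ci_high)
    }


def dissociation_study(
    ac: pipeline.AlignedCohort,
    basis,
    seed: int = 0,
    cfg: DecodingConfig = DESK_CFG,
    n_rep: int = 8,
) -> DissociationResult:
    """Evaluate motion- and avoid-dimension removal for the AV and ITI settings."""
    Xa, ya, _ = pipeline.avoid_error_dataset(ac)
    Xi, yi = pipeline.iti_dataset(ac)
    out = {}
    for name, dims in (("motion", basis.vectors[:, :2]), ("avoid", basis.vectors[:, 2:4])):
        for setting, X, y in (("av", Xa, ya), ("iti", Xi, yi)):
            rc = remove_and_evaluate(
                X, y, dims, cfg, seed=seed, n_rep=n_rep, setting=f"{setting}-{name}"
            )
            s = _curve_summary(rc)
            out[f"{setting}_baseline"] = s[0]
            out[f"{setting}_{name}_removed"] = s[2]
    return DissociationResult(
        av_baseline=out["av_baseline"],
        av_motion_removed=out["av_motion_removed"],
        av_avoid_removed=out["av_avoid_removed"],
        iti_baseline=out["iti_baseline"],
        iti_motion_removed=out["iti_motion_removed"],
        iti_avoid_removed=out["iti_avoid_removed"],
    )


def tone_removal_study(
    ac: pipeline.AlignedCohort,
    basis,
    seed: int = 0,
    cfg: DecodingConfig = DESK_CFG,
    n_rep: int = 8,
) -> dict[str, tuple[float, float, float]]:
    """Tone-vs-nontone decoding before/after removing the tone dimension.

    The tone class is the first 4 s of avoid and error trials after tone
    start; the nontone class is event-free random ITI windows.
    """
    tone = np.concatenate(
        [ac.decode["tone-task1"], ac.decode["tone-task2"]], axis=0
    )[:, :, 5:25]
    nontone = ac.decode["ITI-random"]
    X = np.concatenate([tone, nontone], axis=0)
    y = np.concatenate([np.ones(len(tone)), np.zeros(len(nontone))])
    rc = remove_and_evaluate(
        X, y, basis.vectors[:, 4:5], cfg, seed=seed, n_rep=n_rep, setting="tone"
    )
    s = _curve_summary(rc)
    return {"baseline": s[0], "tone_removed": s[1]}


def null_calibration_study(
    n_runs: int = 20,
    base_seed: int = 0,
    cfg: DecodingConfig | None = None,
    n_rep: int = 10,
) -> dict[str, float]:
    """Fraction of runs whose time-averaged decoding CI contains chance.

    A single cohort with every planted effect set to zero is analysed
    ``n_runs`` times (fresh alignment split, pseudoshuttles and trial
    samples per run); for both the avoid-vs-error and the ITI settings
    the run passes when the 95% CI of the time-averaged accuracy contains
    0.5.
    """
    cfg = cfg if cfg is not None else DecodingConfig(n_per_class=100, n_repetitions=n_rep)
    master = np.random.default_rng(base_seed)
    cohort, _ = generate_cohort(spec=LatentSpec(effect_size=0.0), seed=_sub_seed(master))
    contains = {"av": 0, "iti": 0}
    for _ in range(n_runs):
        rng = np.random.default_rng(_sub_seed(master))
        ac = pipeline.align_cohort(cohort, rng)
        Xa, ya, _ = pipeline.avoid_error_dataset(ac)
        Xi, yi = pipeline.iti_dataset(ac)
        for key, X, y in (("av", Xa, ya), ("iti", Xi, yi)):
            result = repeat_with_ci(
                lambda r: np.nanmean(decode_timesteps(X, y, cfg, r)),
                n_rep=n_rep,
                seed=_sub_seed(master),
            )
            lo, hi = rank_ci(result.values.ravel())
            contains[key] += int(lo <= 0.5 <= hi)
    return {k: v / n_runs for k, v in contains.items()}


@dataclass
class VarianceSummary:
    coding_ve_trials: float  # 5 coding dims, avoid+error averages
    motion_ve_iti: float  # 2 motion dims, ITI shuttle averages
    avoid_ve_iti: float  # 2 avoid dims, ITI shuttle averages


def variance_study(ac: pipeline.AlignedCohort, basis) -> VarianceSummary:
    """Variance captured by the coding dimensions, as fractions of the
    within-subspace variance of condition-average trajectories."""
    trial_avg = np.concatenate(
        [
            ac.decode[c].mean(axis=0)
            for c in ("avoid-task1", "avoid-task2", "error-task1", "error-task2")
        ],
        axis=1,
    )
    trial_avg = trial_avg - trial_avg.mean(axis=1, keepdims=True)
    table = variance_by_dimension(trial_avg, basis).set_index("dimension")
    coding_ve = float(1.0 - table.loc["residual", "relative"])

    iti_avg = pipeline.iti_condition_average(ac)
    iti_avg = iti_avg - iti_avg.mean(axis=1, keepdims=True)
    iti_table = variance_by_dimension(iti_avg, basis).set_index("dimension")
    motion_ve = float(iti_table.loc[["motion-1", "motion-2"], "relative"].sum())
    avoid_ve = float(iti_table.loc[["avoid-1", "avoid-2"], "relative"].sum())
    return VarianceSummary(
        coding_ve_trials=coding_ve, motion_ve_iti=motion_ve, avoid_ve_iti=avoid_ve
    )


@dataclass
class ToneDropSummary:
    tone_correlation: float
    drop_point_lag_steps: int
    drop_pct_at_lag: float


def tone_drop_study(
    cohort,
    ac: pipeline.AlignedCohort,
    basis,
    rng: np.random.Generator,
    lag_steps: int = 6,
) -> ToneDropSummary:
    """Tone-dimension dynamics around the action.

    * correlation between the continuous tone-dimension projection and
      the binary tone trace (averaged over subjects);
    * the maximal-drop time step of the shuttle-aligned avoid-trial
      average, relative to shuttle start;
    * the activity drop (%) at ``lag_steps`` after action onset for
      task-2 X-shuttle error trials versus matched no-shuttle error
      trials.

    The tone dimension is oriented so that its session-wide projection
    correlates positively with the tone trace.
    """
    tone_vec = basis.vectors[:, 4].copy()
    # orientation + correlation, averaged over subjects
    cors = []
    for s, subject in enumerate(cohort.subjects):
        traj = tone_vec @ (ac.subspace.projections[s].T @ subject.traces)
        cors.append(float(np.corrcoef(traj, subject.tone)[0, 1]))
    if np.mean(cors) < 0:
        tone_vec = -tone_vec
        cors = [-c for c in cors]
    tone_correlation = float(np.mean(cors))

    # shuttle-aligned avoid-trial average over the [-3 s, 1 s) window
    avoid_proj = np.concatenate(
        [ac.decode["avoid-task1"], ac.decode["avoid-task2"]], axis=0
    )[:, :, 20:]
    course = tone_vec @ avoid_proj.mean(axis=0)
    align_index = 15  # -3 s window start at 5 Hz
    drop_lag = max_drop_point(course) - align_index

    # task-2 X-shuttle errors vs matched no-shuttle errors, tone-dim value
    shuttle_vals, noshuttle_vals = [], []
    window = (-1.0, 2.0)
    for s, subject in enumerate(cohort.subjects):
        trials = subject.trials
        xerr = trials[
            (trials["type"] == "error")
            & (trials["task"] == 2)
            & (trials["shuttle_class"] == "X")
        ].copy()
        noerr = trials[
            (trials["type"] == "error") & (trials["task"] == 2) & (trials["shuttle_class"] == "")
        ].copy()
        if xerr.empty or noerr.empty:
            continue
        xerr["align_time"] = xerr["shuttle_time"]
        latencies = (xerr["shuttle_time"] - xerr["tone_on"]).to_numpy()
        noerr["align_time"] = noerr["tone_on"] + sample_pseudoshuttle(
            latencies, len(noerr), rng
        )
        proj = ac.subspace.projections[s]
        for frame, store in ((xerr, shuttle_vals), (noerr, noshuttle_vals)):
            tensor = extract_windows(subject.traces, frame, "shuttle-start", window)
            if len(tensor.trial_ids):
                comp = np.einsum("k,ck,tcx->tx", tone_vec, proj, tensor.data)
                store.append(comp)
    shuttle_curve = np.concatenate(shuttle_vals, axis=0).mean(axis=0)
    noshuttle_curve = np.concatenate(noshuttle_vals, axis=0).mean(axis=0)
    i_lag = int(round(-window[0] * 5.0)) + lag_steps
    drop = drop_percentage(noshuttle_curve[i_lag], shuttle_curve[i_lag])
    return ToneDropSummary(
        tone_correlation=tone_correlation,
        drop_point_lag_steps=int(drop_lag),
        drop_pct_at_lag=float(drop),
    )
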