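"""Serialization: cohorts to HDF5/CSV, subspaces and bases to HDF5 + JSON."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .alignment import JointSubspace
from .decoding import DecoderCurve
from .decomposition import CodingBasis
from .synthetic import CohortDataset, SubjectData


def save_cohort(cohort: CohortDataset, out_dir: str | Path) -> None:
    """Write a cohort: one HDF5 per subject plus a pooled trial-table CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tables = []
    for s in cohort.subjects:
        with h5py.File(out_dir / f"{s.subject}.h5", "w") as f:
            f.create_dataset("traces", data=s.traces, compression="gzip")
            f.create_dataset("tracking", data=s.tracking, compression="gzip")
            f.create_dataset("tone", data=s.tone, compression="gzip")
            f.attrs["fs"] = s.fs
            f.attrs["subject"] = s.subject
            f.attrs["point_labels"] = list(s.point_labels)
            grp = f.create_group("session_bounds")
            for day, (a, b) in s.session_bounds.items():
                grp.attrs[str(day)] = (a, b)
        tables.append(s.trials)
    pd.concat(tables, ignore_index=True).to_csv(out_dir / "trials.csv", index=False)


def load_cohort(out_dir: str | Path) -> CohortDataset:
    out_dir = Path(out_dir)
    trials = pd.read_csv(out_dir / "trials.csv", keep_default_na=False)
    for col in ("align_time", "shuttle_time", "tone_on", "tone_off"):
        if col in trials:
            trials[col] = pd.to_numeric(trials[col], errors="coerce")
    subjects = []
    for path in sorted(out_dir.glob("*.h5")):
        with h5py.File(path, "r") as f:
            bounds = {
                int(day): tuple(int(x) for x in ab)
                for day, ab in f["session_bounds"].attrs.items()
            }
            subject = str(f.attrs["subject"])
            subjects.append(
                SubjectData(
                    subject=subject,
                    traces=f["traces"][:],
                    tracking=f["tracking"][:],
                    point_labels=tuple(f.attrs["point_labels"]),
                    tone=f["tone"][:],
                    trials=trials[trials["subject"] == subject].reset_index(drop=True),
                    session_bounds=bounds,
                    fs=float(f.attrs["fs"]),
                )
            )
    return CohortDataset(subjects=subjects)


def save_subspace(subspace: JointSubspace, path: str | Path, **metadata) -> None:
    """Joint subspace to HDF5, with a JSON metadata sidecar."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("coefficients", data=subspace.coefficients)
        for s, p in enumerate(subspace.projections):
            f.create_dataset(f"projections/{s}", data=p)
        f.attrs["k"] = subspace.k
        f.attrs["subject_slices"] = [
            (sl.start, sl.stop) for sl in subspace.subject_slices
        ]
    path.with_suffix(".json").write_text(
        json.dumps({"k": subspace.k, **metadata}, indent=2)
    )


def load_subspace(path: str | Path) -> JointSubspace:
    with h5py.File(path, "r") as f:
        n_sub = len(f["projections"])
        return JointSubspace(
            k=int(f.attrs["k"]),
            coefficients=f["coefficients"][:],
            projections=[f[f"projections/{s}"][:] for s in range(n_sub)],
            subject_slices=[slice(a, b) for a, b in f.attrs["subject_slices"]],
        )


def save_basis(basis: CodingBasis, path: str | Path, **provenance) -> None:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("vectors", data=basis.vectors)
        f.create_dataset("residual", data=basis.residual)
        f.attrs["labels"] = list(basis.labels)
    path.with_suffix(".json").write_text(json.dumps(provenance, indent=2))


def load_basis(path: str | Path) -> CodingBasis:
    with h5py.File(path, "r") as f:
        return CodingBasis(
            vectors=f["vectors"][:],
            labels=tuple(f.attrs["labels"]),
            residual=f["residual"][:],
        )


def curve_to_frame(curve: DecoderCurve) -> pd.DataFrame:
    """Tidy CSV-ready table: time, mean, ci_low, ci_high, setting."""
    lo, hi = curve.ci
    return pd.DataFrame(
        {
            "time": curve.times,
            "mean": curve.mean,
            "ci_low": lo,
            "ci_high": hi,
            "setting": curve.setting,
        }
    )
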