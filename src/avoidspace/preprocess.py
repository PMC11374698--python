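"""Movie-level preprocessing for one-photon calcium imaging.

Order of operations for a registered movie: block-average downsampling,
rank-2 bleaching-trend removal, wide-field luminosity normalisation by a
spatial lowpass ratio, ΔF/F conversion; concatenated multi-session traces
are then brought to a common scale by matching session standard deviations.
A duplicate-cell filter removes components that split one neuron into two.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage


def compute_dff(movie: np.ndarray, epsilon: float = 1e-12) -> np.ndarray:
    """Convert a movie to relative fluorescence change ΔF/F.

    ``dff[t] = (F[t] - F0) / F0`` with ``F0`` the per-pixel mean over the
    whole movie, so the output has zero temporal mean at every pixel.

    Raises
    ------
    ValueError
        If any pixel's F0 is ≤ ``epsilon`` (division would blow up); the
        message reports how many pixels are affected.
    """
    movie = np.asarray(movie, dtype=float)
    f0 = movie.mean(axis=0)
    bad = int(np.sum(f0 <= epsilon))
    if bad:
        raise ValueError(
            f"F0 is <= {epsilon} at {bad} pixel(s); add a baseline offset "
            "or mask these pixels before ΔF/F conversion"
        )
    return (movie - f0) / f0


def remove_bleach(
    movie: np.ndarray, smoothing_window: int = 50, rank: int = 2
) -> np.ndarray:
    """Subtract a low-rank bleaching model fitted on a temporally smoothed movie.

    The movie (time x H x W, or time x pixels) is boxcar-smoothed along
    time, a rank-``rank`` PCA model (mean plus leading spatial components)
    is fitted to the smoothed movie, and the original movie's projection
    onto that model is subtracted.  Slow wide-field trends such as
    photobleaching live in this subspace; fast cellular transients are
    mostly orthogonal to it and survive.

    Notes
    -----
    The residual equals the mean-removed movie times an orthogonal
    projector, so total variance never increases.  A movie whose smoothed
    version has fewer than ``rank`` nonzero singular values is fitted with
    the available rank (with a warning).
    """
    movie = np.asarray(movie, dtype=float)
    if movie.shape[0] <= smoothing_window:
        raise ValueError(
            f"movie length {movie.shape[0]} must exceed smoothing_window "
            f"{smoothing_window}"
        )
    shape = movie.shape
    flat = movie.reshape(shape[0], -1)
    smoothed = ndimage.uniform_filter1d(flat, size=smoothing_window, axis=0, mode="nearest")
    mean = smoothed.mean(axis=0)
    centered = smoothed - mean
    # spatial components of the smoothed movie (right singular vectors)
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    nonzero = int(np.sum(svals > svals[0] * 1e-12)) if svals.size and svals[0] > 0 else 0
    use = min(rank, nonzero)
    if use < rank:
        warnings.warn(
            f"bleach model rank reduced to {use}: smoothed movie has only "
            f"{nonzero} nonzero singular value(s)",
            stacklevel=2,
        )
    basis = vt[:use]  # use x pixels
    resid = flat - mean
    model = mean + (resid @ basis.T) @ basis if use else np.broadcast_to(mean, flat.shape)
    return (flat - model).reshape(shape)


def lowpass_normalize(frame: np.ndarray, sigma: float = 7.0) -> np.ndarray:
    """Divide a frame by its Gaussian-lowpassed version.

    Removes wide-field luminosity fluctuations (e.g. neuropil signal) that
    vary slowly over space; the ratio is invariant to a global rescaling of
    the input.  Must be applied to raw-intensity (strictly positive)
    frames, before ΔF/F conversion.
    """
    frame = np.asarray(frame, dtype=float)
    low = ndimage.gaussian_filter(frame, sigma=sigma, mode="reflect")
    if np.any(low <= 0):
        raise ValueError(
            "lowpass-filtered frame has nonpositive values; "
            "lowpass_normalize requires strictly positive raw intensities"
        )
    return frame / low


def scale_sessions(traces_by_session: list[np.ndarray]) -> list[np.ndarray]:
    """Scale each session to the minimal overall standard deviation.

    Each session's array is multiplied by ``min_s sd_s / sd_session`` so the
    concatenation has a stable s.d. across sessions (differences in imaging
    signal-to-noise between days otherwise dominate joint analyses).
    """
    if not traces_by_session:
        raise ValueError("at least one session required")
    sds = np.array([np.std(s) for s in traces_by_session])
    if np.any(sds == 0):
        raise ValueError("zero-variance session cannot be scaled")
    target = sds.min()
    return [s * (target / sd) for s, sd in zip(traces_by_session, sds)]


def find_duplicate_cells(
    traces: np.ndarray,
    centroids: np.ndarray,
    corr_threshold: float = 0.7,
    dist_threshold_px: float = 20.0,
) -> set[int]:
    """Indices of cells to exclude as duplicates of another cell.

    Cell-extraction algorithms occasionally split one neuron into two
    components.  A pair is flagged when its traces have Pearson correlation
    strictly above ``corr_threshold`` *and* its centroids are strictly
    closer than ``dist_threshold_px``; the member with the smaller trace
    s.d. is excluded.  Chains are handled greedily so the kept set contains
    no remaining flagged pair.
    """
    traces = np.atleast_2d(np.asarray(traces, dtype=float))
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    n = traces.shape[0]
    if n == 0:
        raise ValueError("at least one cell required")
    sds = traces.std(axis=1)
    constant = sds == 0
    if np.any(constant):
        warnings.warn(
            f"{int(constant.sum())} cell(s) have constant traces; "
            "treated as uncorrelated with every other cell",
            stacklevel=2,
        )
    excluded: set[int] = set()
    # greedy pass ordered by trace s.d. descending: strongest cells claim
    # their duplicates, so for a chain A~B~C no flagged pair survives
    order = np.argsort(-sds, kind="stable")
    for a in order:
        if a in excluded:
            continue
        for b in range(n):
            if b == a or b in excluded or constant[a] or constant[b]:
                continue
            dist = np.linalg.norm(centroids[a] - centroids[b])
            if dist >= dist_threshold_px:
                continue
            r = np.corrcoef(traces[a], traces[b])[0, 1]
            if r > corr_threshold:
                excluded.add(int(b) if sds[a] >= sds[b] else int(a))
    return excluded


def block_downsample(
    movie: np.ndarray, spatial: int = 2, temporal: int = 4
) -> np.ndarray:
    """Block-average a movie by integer factors in space and time.

    Default factors mirror a 1000x1000 px, 20 Hz acquisition reduced to
    500x500 px at 5 Hz.  Trailing samples that do not fill a block are
    dropped.
    """
    movie = np.asarray(movie, dtype=float)
    t, h, w = movie.shape
    t2, h2, w2 = t // temporal, h // spatial, w // spatial
    if t2 == 0 or h2 == 0 or w2 == 0:
        raise ValueError("movie smaller than one block")
    m = movie[: t2 * temporal, : h2 * spatial, : w2 * spatial]
    m = m.reshape(t2, temporal, h2, spatial, w2, spatial)
    return m.mean(axis=(1, 3, 5))
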