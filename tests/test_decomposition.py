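"""Coding-dimension decomposition: nullspaces, iterative decoders, removal."""

import numpy as np
import pytest

from avoidspace.decoding import DecodingConfig
from avoidspace.decomposition import (
    CodingBasis,
    avoid_dimensions,
    build_coding_basis,
    evaluate_decoder_by_day,
    motion_dimensions,
    nullspace_basis,
    nullspace_project,
    remove_and_evaluate,
    tone_dimension,
)


def _orthonormal(rng, k, r):
    return np.linalg.qr(rng.standard_normal((k, r)))[0]


def _gram_schmidt_complement(dims):
    """Brute-force completion of `dims` to a basis; returns the complement."""
    k = dims.shape[0]
    basis = [dims[:, j] for j in range(dims.shape[1])]
    for e in np.eye(k):
        v = e.copy()
        for b in basis:
            v -= (v @ b) * b
        if np.linalg.norm(v) > 1e-10:
            basis.append(v / np.linalg.norm(v))
    return np.stack(basis[dims.shape[1] :], axis=1)


class TestNullspaceProject:
    def test_removed_components_vanish(self):
        rng = np.random.default_rng(0)
        dims = _orthonormal(rng, 10, 3)
        x = rng.standard_normal((10, 40))
        out = nullspace_project(x, dims)
        np.testing.assert_allclose(dims.T @ out, 0.0, atol=1e-12)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        dims = _orthonormal(rng, 8, 2)
        x = rng.standard_normal((5, 8, 12))
        once = nullspace_project(x, dims, axis=1)
        twice = nullspace_project(once, dims, axis=1)
        np.testing.assert_allclose(once, twice, atol=1e-12)

    def test_full_basis_removes_everything(self):
        rng = np.random.default_rng(2)
        dims = _orthonormal(rng, 6, 6)
        x = rng.standard_normal((6, 20))
        np.testing.assert_allclose(nullspace_project(x, dims), 0.0, atol=1e-12)

    def test_norm_never_increases(self):
        rng = np.random.default_rng(3)
        dims = _orthonormal(rng, 7, 3)
        x = rng.standard_normal((7, 30))
        assert np.linalg.norm(nullspace_project(x, dims)) <= np.linalg.norm(x)

    def test_non_orthonormal_dims_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(ValueError, match="orthonormal"):
            nullspace_project(rng.random((5, 10)), rng.random((5, 2)))

    def test_matches_gram_schmidt_oracle(self):
        """Projector equals reconstruction from a brute-force complement basis."""
        rng = np.random.default_rng(5)
        dims = _orthonormal(rng, 9, 4)
        comp = _gram_schmidt_complement(dims)
        x = rng.standard_normal((9, 25))
        np.testing.assert_allclose(
            nullspace_project(x, dims), comp @ (comp.T @ x), atol=1e-10
        )
        # the library's complement spans the same space
        lib = nullspace_basis(dims)
        cos = np.linalg.svd(lib.T @ comp, compute_uv=False)
        assert np.all(1.0 - cos < 1e-10)


class TestMotionDimensions:
    def test_single_planted_latent_recovered(self):
        rng = np.random.default_rng(6)
        direction = _orthonormal(rng, 10, 1)[:, 0]
        course = np.sin(np.linspace(0, 3 * np.pi, 80))
        avg = np.outer(direction, course)
        dims = motion_dimensions(avg, n_dims=1)
        angle = np.degrees(np.arccos(np.clip(abs(dims[:, 0] @ direction), -1, 1)))
        assert angle < 1.0

    def test_output_orthonormal(self):
        rng = np.random.default_rng(7)
        dims = motion_dimensions(rng.standard_normal((10, 80)), n_dims=5)
        np.testing.assert_allclose(dims.T @ dims, np.eye(5), atol=1e-10)

    def test_rank_deficient_input_warns(self):
        rng = np.random.default_rng(8)
        avg = np.outer(rng.standard_normal(10), rng.standard_normal(80))
        with pytest.warns(UserWarning, match="rank"):
            dims = motion_dimensions(avg, n_dims=5)
        assert dims.shape[1] == 1

    def test_eventless_average_warns(self):
        with pytest.warns(UserWarning, match="no variance"):
            dims = motion_dimensions(np.zeros((10, 80)), n_dims=2)
        assert dims.shape == (10, 0)


def _planted_trial_data(rng, direction, n_trials=200, k=10, n_time=20, snr=4.0):
    """Avoid/error-style data: class 1 carries a ramp along `direction`."""
    X = 0.25 * rng.standard_normal((n_trials, k, n_time))
    y = np.repeat([0, 1], n_trials // 2)
    ramp = np.linspace(0, 1, n_time) * snr * 0.25
    X[y == 1] += direction[None, :, None] * ramp[None, None, :]
    return X, y


class TestAvoidDimensions:
    def test_planted_direction_recovered(self):
        rng = np.random.default_rng(9)
        motion = _orthonormal(rng, 10, 2)
        direction = nullspace_basis(motion)[:, 0]  # orthogonal to motion dims
        X, y = _planted_trial_data(rng, direction)
        dims = avoid_dimensions(X, y, motion, n_dims=1, rng=rng, n_reps=40)
        angle = np.degrees(np.arccos(np.clip(abs(dims[:, 0] @ direction), -1, 1)))
        assert angle < 10.0

    def test_orthogonality_chain(self):
        rng = np.random.default_rng(10)
        motion = _orthonormal(rng, 10, 2)
        X = rng.standard_normal((100, 10, 8))
        y = np.repeat([0, 1], 50)
        dims = avoid_dimensions(X, y, motion, n_dims=3, rng=rng, n_reps=5)
        full = np.concatenate([motion, dims], axis=1)
        np.testing.assert_allclose(full.T @ full, np.eye(5), atol=1e-8)


class TestToneDimension:
    def test_planted_step_recovered_and_orthogonal(self):
        rng = np.random.default_rng(11)
        prior = _orthonormal(rng, 10, 4)
        direction = nullspace_basis(prior)[:, 0]
        n = 150
        tone = 0.25 * rng.standard_normal((n, 10, 25)) + direction[None, :, None]
        base = 0.25 * rng.standard_normal((n, 10, 5))
        valid = np.ones((n, 25), dtype=bool)
        v = tone_dimension(tone, valid, base, prior, rng=rng, n_reps=30)
        np.testing.assert_allclose(prior.T @ v, 0.0, atol=1e-8)
        angle = np.degrees(np.arccos(np.clip(abs(v @ direction), -1, 1)))
        assert angle < 10.0

    def test_no_valid_tone_samples_rejected(self):
        rng = np.random.default_rng(12)
        prior = _orthonormal(rng, 10, 4)
        tone = rng.random((5, 10, 8))
        base = rng.random((5, 10, 5))
        with pytest.raises(ValueError, match="no pre-shuttle"):
            tone_dimension(tone, np.zeros((5, 8), dtype=bool), base, prior)


class TestCodingBasis:
    def test_full_basis_completeness(self, aligned):
        _, basis, _, _ = aligned
        full = basis.full_basis()
        np.testing.assert_allclose(full.T @ full, np.eye(basis.k), atol=1e-8)
        assert basis.vectors.shape == (basis.k, 5)
        assert basis.residual.shape == (basis.k, basis.k - 5)

    def test_non_orthonormal_vectors_rejected(self):
        rng = np.random.default_rng(13)
        with pytest.raises(ValueError, match="orthonormal"):
            CodingBasis(vectors=rng.random((10, 5)))

    def test_build_from_parts(self):
        rng = np.random.default_rng(14)
        q = _orthonormal(rng, 10, 5)
        basis = build_coding_basis(q[:, :2], q[:, 2:4], q[:, 4])
        assert basis.labels == ("motion-1", "motion-2", "avoid-1", "avoid-2", "tone")


class TestRemoveAndEvaluate:
    def test_removing_everything_collapses_to_chance(self):
        rng = np.random.default_rng(15)
        direction = np.zeros(4)
        direction[0] = 1.0
        X, y = _planted_trial_data(rng, direction, n_trials=80, k=4, n_time=5, snr=8.0)
        basis = np.eye(4)
        cfg = DecodingConfig(n_per_class=30, n_repetitions=4)
        curve = remove_and_evaluate(X, y, basis, cfg, seed=1, n_rep=4)
        assert curve.accuracy[0] > 0.8
        assert abs(curve.accuracy[-1] - 0.5) < 0.1
        assert curve.drop[0] == 0.0

    def test_cannot_remove_more_than_k(self):
        rng = np.random.default_rng(16)
        X = rng.random((40, 3, 4))
        y = np.repeat([0, 1], 20)
        cfg = DecodingConfig(n_per_class=10, n_repetitions=4)
        with pytest.raises(ValueError, match="cannot remove"):
            remove_and_evaluate(X, y, np.eye(3), cfg, max_removed=4)


class TestEvaluateByDay:
    def _data(self, rng, task2_only):
        """700 trials over 4 days; the signal is present on days {6,7} only
        if task2_only, else on all days."""
        n = 700
        days = rng.choice([3, 4, 6, 7], size=n)
        # labels balanced within every day so that day-wise test sets carry
        # no class-frequency information
        y = np.zeros(n, dtype=int)
        for d in (3, 4, 6, 7):
            members = np.flatnonzero(days == d)
            y[members[: len(members) // 2]] = 1
        X = 0.3 * rng.standard_normal((n, 2, 6))
        active = np.isin(days, [6, 7]) if task2_only else np.ones(n, dtype=bool)
        X[(y == 1) & active, 0, :] += 1.0
        return X, y, days

    def test_shared_signal_above_chance_everywhere(self):
        rng = np.random.default_rng(17)
        X, y, days = self._data(rng, task2_only=False)
        cfg = DecodingConfig(n_per_class=150, n_repetitions=5)
        res = evaluate_decoder_by_day(X, y, days, cfg, seed=2, n_rep=20)
        assert res.above_chance.all()
        assert np.all(res.accuracy > 0.5)

    def test_task2_signal_above_chance_on_task2_days_only(self):
        rng = np.random.default_rng(18)
        X, y, days = self._data(rng, task2_only=True)
        cfg = DecodingConfig(n_per_class=150, n_repetitions=5)
        res = evaluate_decoder_by_day(X, y, days, cfg, seed=3, n_rep=20)
        flagged = dict(zip(res.days, res.above_chance))
        assert flagged[6] and flagged[7]
        assert not flagged[3] and not flagged[4]
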