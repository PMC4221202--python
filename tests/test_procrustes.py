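"""Superimposition against closed forms, grid searches, and a long-run oracle."""

import numpy as np
import pytest

from snoutshape.outline import SemilandmarkSet
from snoutshape.procrustes import (
    centroid_size, gpa, optimal_rotation, procrustes_distance,
)


def rotation(angle):
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s], [s, c]])


def grid_search_angle(a, b, step_deg=0.001):
    """Brute-force rotation-angle minimiser of ||A R(t) - B||^2."""
    angles = np.deg2rad(np.arange(0.0, 360.0, step_deg))
    # residual as a function of angle has closed trig form; evaluate densely
    sxx = float(np.sum(a * b))
    sxy = float(np.sum(a[:, 1] * b[:, 0] - a[:, 0] * b[:, 1]))
    norm = np.sum(a**2) + np.sum(b**2)
    resid = norm - 2.0 * (sxx * np.cos(angles) + sxy * np.sin(angles))
    return angles[int(np.argmin(resid))], float(np.sqrt(resid.min()))


class TestCentroidSize:
    def test_unit_square_closed_form(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        assert centroid_size(square) == pytest.approx(np.sqrt(2.0), abs=1e-12)

    def test_homogeneous_in_scale(self, rng):
        config = rng.normal(size=(7, 2))
        assert centroid_size(config * 3.5) == pytest.approx(
            3.5 * centroid_size(config), rel=1e-12
        )

    def test_matches_termwise_summation_oracle(self, rng):
        config = rng.normal(size=(3, 2))
        centroid = config.mean(axis=0)
        total = 0.0
        for point in config:
            total += (point[0] - centroid[0]) ** 2 + (point[1] - centroid[1]) ** 2
        assert centroid_size(config) == pytest.approx(np.sqrt(total), rel=1e-12)

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError, match="coincident"):
            centroid_size(np.ones((4, 2)))


class TestOptimalRotation:
    def test_recovers_90_degrees(self, rng):
        a = rng.normal(size=(6, 2))
        a -= a.mean(axis=0)
        b = a @ rotation(np.pi / 2).T
        r = optimal_rotation(a, b)
        np.testing.assert_allclose(a @ r, b, atol=1e-10)
        assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-10)

    def test_identity_for_identical_configs(self, rng):
        a = rng.normal(size=(5, 2))
        a -= a.mean(axis=0)
        np.testing.assert_allclose(optimal_rotation(a, a), np.eye(2), atol=1e-10)

    def test_matches_grid_search_oracle(self, rng):
        a = rng.normal(size=(5, 2))
        b = rng.normal(size=(5, 2))
        a -= a.mean(axis=0)
        b -= b.mean(axis=0)
        r = optimal_rotation(a, b)
        angle = np.arctan2(r[1, 0], r[0, 0]) % (2 * np.pi)
        grid_angle, grid_resid = grid_search_angle(a, b)
        assert angle == pytest.approx(grid_angle, abs=np.deg2rad(0.002))
        assert np.sqrt(np.sum((a @ r - b) ** 2)) <= grid_resid + 1e-9

    def test_never_reflects(self, rng):
        a = rng.normal(size=(8, 2))
        a -= a.mean(axis=0)
        b = a.copy()
        b[:, 0] *= -1  # reflected target
        assert np.linalg.det(optimal_rotation(a, b)) == pytest.approx(1.0, abs=1e-10)


class TestProcrustesDistance:
    def test_identity_and_symmetry(self, rng):
        a = rng.normal(size=(6, 2))
        a = (a - a.mean(axis=0)) / centroid_size(a)
        b = rng.normal(size=(6, 2))
        b = (b - b.mean(axis=0)) / centroid_size(b)
        assert procrustes_distance(a, a) == pytest.approx(0.0, abs=1e-12)
        assert procrustes_distance(a, b) == pytest.approx(
            procrustes_distance(b, a), abs=1e-12
        )

    def test_triangle_matches_grid_minimum(self, rng):
        a = rng.normal(size=(3, 2))
        b = rng.normal(size=(3, 2))
        a = (a - a.mean(axis=0)) / centroid_size(a)
        b = (b - b.mean(axis=0)) / centroid_size(b)
        _, grid_resid = grid_search_angle(a, b)
        assert procrustes_distance(a, b) == pytest.approx(grid_resid, abs=1e-6)


def nuisance(rng, points):
    return (
        points @ rotation(rng.uniform(0, 2 * np.pi)).T * rng.uniform(0.5, 3.0)
        + rng.normal(size=2) * 10
    )


class TestGpa:
    def test_nuisance_transforms_removed(self, rng):
        base = rng.normal(size=(10, 2))
        shapes = [
            SemilandmarkSet(f"s{i}", nuisance(rng, base)) for i in range(6)
        ]
        aligned = gpa(shapes)
        assert aligned.iterations <= 2
        for i in range(aligned.n):
            for j in range(i + 1, aligned.n):
                d = np.sqrt(np.sum((aligned.configs[i] - aligned.configs[j]) ** 2))
                assert d <= 1e-8

    def test_invariants_of_aligned_configs(self, rng):
        shapes = [SemilandmarkSet(f"s{i}", rng.normal(size=(8, 2))) for i in range(5)]
        aligned = gpa(shapes)
        for config in aligned.configs:
            assert np.linalg.norm(config.mean(axis=0)) < 1e-8
            assert abs(centroid_size(config) - 1.0) < 1e-8
        assert aligned.final_change < 1e-4

    def test_idempotent_consensus(self, rng):
        shapes = [SemilandmarkSet(f"s{i}", rng.normal(size=(8, 2))) for i in range(5)]
        first = gpa(shapes, tolerance=1e-10)
        again = gpa(
            [SemilandmarkSet(i, c) for i, c in zip(first.ids, first.configs)],
            tolerance=1e-10,
        )
        assert procrustes_distance(first.consensus, again.consensus) < 1e-6

    def test_order_and_nuisance_invariance_of_consensus(self, rng):
        base = [rng.normal(size=(7, 2)) for _ in range(5)]
        a = gpa([SemilandmarkSet(f"s{i}", b) for i, b in enumerate(base)],
                tolerance=1e-10)
        shuffled = [SemilandmarkSet(f"s{i}", nuisance(rng, b))
                    for i, b in enumerate(base)][::-1]
        b = gpa(shuffled, tolerance=1e-10)
        assert procrustes_distance(a.consensus, b.consensus) < 1e-6

    def test_mismatched_point_counts_rejected(self, rng):
        shapes = [
            SemilandmarkSet("a", rng.normal(size=(5, 2))),
            SemilandmarkSet("b", rng.normal(size=(6, 2))),
        ]
        with pytest.raises(ValueError, match="points"):
            gpa(shapes)
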