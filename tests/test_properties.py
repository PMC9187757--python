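"""Trajectory descriptors: enclosing circle, shape measures, containment
probability, property PCA."""

import numpy as np
import pytest
import shapely

from conftest import brute_force_mec_radius
from sptmotion import (
    Trajectory,
    TrajectorySet,
    compute_properties,
    immobile_containment_probability,
    minimum_enclosing_circle,
    property_pca,
)
from sptmotion.errors import DomainError
from sptmotion.properties import read_property_table, write_property_table

UM = 1e-6


def _set(points, dt=1.0):
    return TrajectorySet(
        [Trajectory("t", np.arange(len(points)), np.asarray(points, float))], dt=dt
    )


class TestMinimumEnclosingCircle:
    @pytest.mark.parametrize(
        "points,centre,radius",
        [
            ([(0, 0)], (0, 0), 0.0),
            ([(0, 0), (2, 0)], (1, 0), 1.0),
            ([(0, 0), (2, 0), (1, 1)], (1, 0), 1.0),  # third point on circle
            ([(0, 0), (2, 0), (1, 0.5)], (1, 0), 1.0),  # interior point
        ],
    )
    def test_known_circles(self, points, centre, radius):
        c, r = minimum_enclosing_circle(np.array(points, float))
        np.testing.assert_allclose(c, centre, atol=1e-12)
        assert r == pytest.approx(radius, abs=1e-12)

    def test_empty_input_is_domain_error(self):
        with pytest.raises(DomainError):
            minimum_enclosing_circle(np.empty((0, 2)))

    def test_matches_brute_force_on_random_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(300):
            n = int(rng.integers(1, 13))
            pts = rng.normal(0, 1.0, size=(n, 2))
            if rng.random() < 0.2 and n >= 2:  # inject duplicates/collinear
                pts[0] = pts[-1]
            c, r = minimum_enclosing_circle(pts)
            assert r == pytest.approx(brute_force_mec_radius(pts), rel=1e-9, abs=1e-12)
            assert np.all(np.linalg.norm(pts - c, axis=1) <= r * (1 + 1e-9) + 1e-15)

    def test_matches_shapely_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            pts = rng.normal(0, 2.0, size=(int(rng.integers(2, 40)), 2))
            _, r = minimum_enclosing_circle(pts)
            ref = shapely.minimum_bounding_radius(shapely.multipoints(pts))
            assert r == pytest.approx(ref, rel=1e-9)

    def test_deterministic(self):
        pts = np.random.default_rng(5).normal(size=(20, 2))
        assert minimum_enclosing_circle(pts)[1] == minimum_enclosing_circle(pts)[1]


class TestComputeProperties:
    def test_straight_path(self):
        tab = compute_properties(_set([(0, 0), (1 * UM, 0), (2 * UM, 0)]))
        row = tab.loc["t"]
        assert row["number_of_points"] == 3
        assert row["length"] == pytest.approx(2 * UM)
        assert row["tortuosity"] == pytest.approx(1.0)
        assert row["elongation"] == pytest.approx(1.0)
        assert row["elongation_angle"] == pytest.approx(0.0, abs=1e-12)

    def test_rectangle_corner_elongation(self):
        # gyration eigenvalues 1 and 0.25 (um^2) -> elongation 0.75
        pts = np.array([(0, 0), (2, 0), (0, 1), (2, 1)], float) * UM
        tab = compute_properties(
            TrajectorySet([Trajectory("t", np.arange(4), pts)], dt=1.0)
        )
        assert tab.loc["t", "elongation"] == pytest.approx(0.75)

    @pytest.mark.parametrize(
        "points,expected_bits",
        [
            ([(0, 0), (10e-9, 10e-9), (20e-9, 0)], 0.0),  # one 100 nm cell
            ([(0, 0), (1 * UM, 0), (0, 1 * UM), (1 * UM, 1 * UM)], 2.0),
        ],
    )
    def test_entropy_limits(self, points, expected_bits):
        tab = compute_properties(_set(points), entropy_bin=1 * UM)
        assert tab.loc["t", "entropy"] == pytest.approx(expected_bits)

    def test_closed_path_has_infinite_tortuosity(self):
        tab = compute_properties(
            _set([(0, 0), (1 * UM, 0), (1 * UM, 1 * UM), (0, 0)])
        )
        assert np.isinf(tab.loc["t", "tortuosity"])

    def test_degenerate_single_point_gives_nan_not_error(self):
        tab = compute_properties(_set([(0, 0)]))
        row = tab.loc["t"]
        assert row["number_of_points"] == 1
        assert np.isnan(row["length"]) and np.isnan(row["elongation"])
        assert row["mbcr"] == 0.0

    def test_mbcc_within_mbcr_and_tortuosity_at_least_one(self, default_sim):
        _, _, filtered = default_sim
        tab = compute_properties(filtered)
        assert np.all(tab["mbcc_com"] <= tab["mbcr"] * (1 + 1e-9))
        tor = tab["tortuosity"].to_numpy()
        assert np.all(tor[np.isfinite(tor)] >= 1 - 1e-12)

    def test_elongation_invariant_under_rotation_and_translation(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(0, 1e-7, size=(15, 2))
        theta = 0.7
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        moved = pts @ R.T + np.array([3e-6, -2e-6])
        a = compute_properties(_set(pts)).loc["t"]
        b = compute_properties(_set(moved)).loc["t"]
        assert b["elongation"] == pytest.approx(a["elongation"], rel=1e-9)
        assert b["mbcr"] == pytest.approx(a["mbcr"], rel=1e-9)

    def test_csv_round_trip(self, tmp_path, default_sim):
        _, _, filtered = default_sim
        tab = compute_properties(filtered)
        write_property_table(tab, tmp_path / "props.csv")
        back = read_property_table(tmp_path / "props.csv")
        assert list(back.index) == list(tab.index)
        np.testing.assert_allclose(
            back["mbcr"].to_numpy(), tab["mbcr"].to_numpy(), rtol=1e-12
        )


class TestContainmentProbability:
    def test_zero_noise_is_certain(self):
        assert immobile_containment_probability(10, 0.0, 1e-9, 100, seed=0) == 1.0

    def test_monotone_in_threshold_and_sigma(self):
        ps = [
            immobile_containment_probability(17, 20e-9, thr, n_mc=3000, seed=2)
            for thr in (40e-9, 80e-9, 120e-9)
        ]
        assert ps == sorted(ps)
        qs = [
            immobile_containment_probability(17, s, 80e-9, n_mc=3000, seed=2)
            for s in (10e-9, 20e-9, 40e-9)
        ]
        assert qs == sorted(qs, reverse=True)

    def test_reproducible_for_fixed_seed(self):
        a = immobile_containment_probability(9, 15e-9, 50e-9, n_mc=2000, seed=11)
        b = immobile_containment_probability(9, 15e-9, 50e-9, n_mc=2000, seed=11)
        assert a == b


class TestPropertyPCA:
    def test_perfectly_correlated_columns_load_on_first_component(self):
        import pandas as pd

        rng = np.random.default_rng(4)
        v = rng.normal(size=200)
        tab = pd.DataFrame({"p1": v, "p2": 3 * v + 1})
        res = property_pca(tab)
        assert res.explained_variance[0] / res.explained_variance.sum() > 0.999

    def test_reconstruction_identity(self):
        import pandas as pd

        rng = np.random.default_rng(5)
        tab = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        res = property_pca(tab)
        X = tab.to_numpy()
        Xs = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
        np.testing.assert_allclose(
            res.scores.to_numpy() @ res.loadings.to_numpy().T, Xs, atol=1e-10
        )
        # orthonormal loadings, non-increasing variances
        L = res.loadings.to_numpy()
        np.testing.assert_allclose(L.T @ L, np.eye(L.shape[1]), atol=1e-10)
        assert np.all(np.diff(res.explained_variance) <= 1e-12)

    def test_constant_column_excluded_with_warning(self):
        import pandas as pd

        rng = np.random.default_rng(6)
        tab = pd.DataFrame(
            {"a": rng.normal(size=30), "b": rng.normal(size=30), "c": 1.0}
        )
        with pytest.warns(UserWarning, match="'c'"):
            res = property_pca(tab)
        assert list(res.loadings.index) == ["a", "b"]
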