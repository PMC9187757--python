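"""Shared fixtures and independent brute-force oracles for the test suite."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from sptmotion import (
    SimConfig,
    Trajectory,
    TrajectorySet,
    filter_min_localizations,
    render_observed,
    simulate_ground_truth,
)

# ---------------------------------------------------------------------------
# oracles (kept deliberately naive and independent of the implementation)


def brute_force_mec_radius(points: np.ndarray) -> float:
    """Minimum enclosing circle radius by exhaustive search.

    Tries every circle defined by one point (r=0), every pair (as
    diameter) and every triple (circumcircle), keeps the smallest circle
    containing all points.  O(n^4); oracle only.
    """
    pts = np.asarray(points, dtype=float)[:, :2]
    n = len(pts)
    best = np.inf
    candidates = []
    for i in range(n):
        candidates.append((pts[i], 0.0))
    for i, j in combinations(range(n), 2):
        c = (pts[i] + pts[j]) / 2
        candidates.append((c, np.linalg.norm(pts[i] - c)))
    for i, j, k in combinations(range(n), 3):
        (ax, ay), (bx, by), (cx, cy) = pts[i], pts[j], pts[k]
        d = 2.0 * (ax * (by - cy) + bx * (cy - ay) + cx * (ay - by))
        if d == 0.0:
            continue
        a2, b2, c2 = ax * ax + ay * ay, bx * bx + by * by, cx * cx + cy * cy
        ux = (a2 * (by - cy) + b2 * (cy - ay) + c2 * (ay - by)) / d
        uy = (a2 * (cx - bx) + b2 * (ax - cx) + c2 * (bx - ax)) / d
        centre = np.array([ux, uy])
        candidates.append((centre, np.linalg.norm(pts[i] - centre)))
    for centre, r in candidates:
        if r < best and np.all(
            np.linalg.norm(pts - centre, axis=1) <= r * (1 + 1e-9) + 1e-30
        ):
            best = r
    return float(best)


def brute_force_t_msd(frames: np.ndarray, coords: np.ndarray):
    """Direct double-loop T-MSD: mean |x_j - x_i|^2 over pairs with frame
    difference n, for every n that occurs.  Returns {lag: msd}."""
    out: dict[int, list[float]] = {}
    n = len(frames)
    for i in range(n):
        for j in range(i + 1, n):
            lag = int(frames[j] - frames[i])
            out.setdefault(lag, []).append(float(np.sum((coords[j] - coords[i]) ** 2)))
    return {lag: float(np.mean(v)) for lag, v in out.items()}


def brute_force_te_msd(trajs: list[Trajectory]):
    """Direct evaluation of the time-ensemble average: per-trajectory T-MSD
    first, then the unweighted mean over trajectories present at each lag."""
    per_traj = [brute_force_t_msd(t.frames, t.coords) for t in trajs if t.n_points >= 2]
    lags = sorted({lag for d in per_traj for lag in d})
    return {
        lag: float(np.mean([d[lag] for d in per_traj if lag in d])) for lag in lags
    }


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def default_sim():
    """One default-scale simulation: (truth, observed, filtered) at seed 7."""
    cfg = SimConfig(seed=7)
    truth = simulate_ground_truth(cfg)
    observed = render_observed(truth, cfg)
    filtered = filter_min_localizations(observed, 5)
    return truth, observed, filtered


@pytest.fixture()
def straight_line_set():
    """Two deterministic collinear trajectories in micrometres."""
    um = 1e-6
    t1 = Trajectory("a", [0, 1, 2, 3], np.array([[0, 0], [1, 0], [2, 0], [3, 0]]) * um)
    t2 = Trajectory("b", [0, 1, 2], np.array([[0, 0], [0, 1], [0, 2]]) * um)
    return TrajectorySet([t1, t2], dt=1.0)


def random_trajectory(rng: np.random.Generator, max_points: int = 8) -> Trajectory:
    """A random short trajectory, possibly with frame gaps."""
    n = int(rng.integers(2, max_points + 1))
    frames = np.sort(rng.choice(np.arange(3 * max_points), size=n, replace=False))
    coords = rng.normal(0.0, 1e-7, size=(n, 2))
    return Trajectory(f"r{rng.integers(1 << 30)}", frames, coords)
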