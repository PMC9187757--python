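"""Mean-squared-displacement analysis with noise corrections.

Two complementary estimators are provided.  The time-averaged MSD (T-MSD)
of a single trajectory at delay ``t_n = n * dt`` averages the squared
displacement over every pair of localizations ``n`` frames apart.  The
time-ensemble-averaged MSD (TE-MSD) averages the per-trajectory T-MSD over
all trajectories long enough to contribute at each delay, weighting each
trajectory equally; it strongly reduces the single-trajectory bias that
makes short-track MSD fits unreliable, at the price of mixing trajectories
of different lengths at long delays.

For free 2-D normal diffusion observed with localization error ``sigma``
and motion blur, the measured curve is

    MSD(t_n) = 4 D t_n + 4 (sigma^2 - 2 R D dt)

so a straight-line fit over the shortest delays yields the diffusion
coefficient from the slope and, given the motion-blur coefficient ``R``,
the localization error from the intercept.  ``R`` depends only on the
camera shutter profile: 0 for an instantaneous exposure, 1/6 for a shutter
open during the entire frame, and at most 1/4 in general.

Delay lags are defined on frame-index differences, so trajectories with
gaps (missed detections bridged by the tracker) contribute each lag they
actually span.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
from scipy import integrate

from .errors import DomainError, FitError
from .trajectory_io import Trajectory, TrajectorySet

__all__ = [
    "MSDCurve",
    "MSDFitResult",
    "t_msd",
    "te_msd",
    "fit_msd_linear",
    "motion_blur_coefficient",
    "uniform_exposure",
    "instantaneous_exposure",
    "per_trajectory_D",
]

TIME_AVERAGED = "time-averaged"
TIME_ENSEMBLE_AVERAGED = "time-ensemble-averaged"


@dataclass(frozen=True)
class MSDCurve:
    """An MSD curve: values and contribution counts per delay.

    ``lags`` are frame-index differences ``n``; ``delays`` are ``n * dt``
    in seconds.  ``counts`` holds the number of displacement pairs per lag
    for a T-MSD curve, or the number of contributing trajectories ``J_n``
    for a TE-MSD curve.
    """

    lags: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    dt: float
    kind: str = TIME_AVERAGED
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        lags = np.asarray(self.lags, dtype=np.int64)
        values = np.asarray(self.values, dtype=np.float64)
        counts = np.asarray(self.counts, dtype=np.int64)
        if not (len(lags) == len(values) == len(counts)):
            raise DomainError("lags, values, counts must have equal length")
        if self.se is not None:
            se = np.asarray(self.se, dtype=np.float64)
            if len(se) != len(lags):
                raise DomainError("se must match lags in length")
            object.__setattr__(self, "se", se)
        if len(lags) == 0:
            raise DomainError("empty MSD curve")
        if lags[0] < 1 or (len(lags) > 1 and not np.all(np.diff(lags) > 0)):
            raise DomainError("lags must be positive and strictly increasing")
        if np.any(values < 0) or np.any(counts < 1):
            raise DomainError("MSD values must be >= 0 and counts >= 1")
        if not self.dt > 0:
            raise DomainError("dt must be positive")
        if self.kind not in (TIME_AVERAGED, TIME_ENSEMBLE_AVERAGED):
            raise DomainError(f"unknown MSD kind {self.kind!r}")
        object.__setattr__(self, "lags", lags)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "counts", counts)

    @property
    def delays(self) -> np.ndarray:
        """Delay times ``t_n = n * dt`` in seconds."""
        return self.lags * self.dt

    def __len__(self) -> int:
        return len(self.lags)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"delay_s": self.delays, "msd_m2": self.values, "count": self.counts}
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class MSDFitResult:
    """Result of a straight-line MSD fit.

    ``D`` in m^2 s^-1 (may be negative for noise-dominated tracks — such
    estimates are reported, not clipped); ``intercept`` in m^2; ``sigma``
    is the localization error recovered from the intercept, or ``None``
    when the blur-corrected intercept is negative and no real solution
    exists.  ``R`` is the motion-blur coefficient supplied to the fit, not
    estimated (a single intercept cannot separate ``sigma`` and ``R``).
    """

    D: float
    intercept: float
    se_D: float
    se_intercept: float
    sigma: float | None
    R: float
    n_points_used: int
    d: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.R <= 0.25):
            raise DomainError(f"R must be in [0, 0.25], got {self.R}")
        if self.n_points_used < 3:
            raise DomainError("n_points_used must be >= 3")

    def to_dict(self) -> dict:
        return {
            "D": self.D,
            "intercept": self.intercept,
            "se_D": self.se_D,
            "se_intercept": self.se_intercept,
            "sigma": self.sigma,
            "R": self.R,
            "n_points_used": self.n_points_used,
            "d": self.d,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _pair_sums(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """Sum of squared displacements and pair counts per frame lag."""
    f = traj.frames
    x = traj.coords
    n = len(f)
    lag = (f[None, :] - f[:, None])[np.triu_indices(n, k=1)]
    diff = x[None, :, :] - x[:, None, :]
    sq = (diff**2).sum(axis=2)[np.triu_indices(n, k=1)]
    nmax = int(lag.max())
    sums = np.bincount(lag, weights=sq, minlength=nmax + 1)
    counts = np.bincount(lag, minlength=nmax + 1)
    return sums, counts


def t_msd(traj: Trajectory, dt: float) -> MSDCurve:
    """Time-averaged MSD of one trajectory.

    At each frame lag ``n`` with at least one localization pair, the value
    is the mean of ``|x_{i+n} - x_i|^2`` over all such pairs; lags spanned
    by no pair (gaps) are omitted.
    """
    if traj.n_points < 2:
        raise DomainError(f"trajectory {traj.id!r}: T-MSD needs >= 2 localizations")
    sums, counts = _pair_sums(traj)
    lags = np.flatnonzero(counts)
    return MSDCurve(lags, sums[lags] / counts[lags], counts[lags], dt, TIME_AVERAGED)


def te_msd(set_: TrajectorySet) -> MSDCurve:
    """Time-ensemble-averaged MSD of a trajectory set.

    At each lag the value is the unweighted mean, over the ``J_n``
    trajectories that span that lag, of the per-trajectory T-MSD — each
    trajectory counts equally regardless of its length.  ``counts`` holds
    ``J_n`` and ``se`` the standard error of the mean across the ``J_n``
    contributing trajectories (NaN where ``J_n == 1``).
    """
    per_lag: dict[int, list[float]] = {}
    any_ok = False
    for traj in set_.trajectories:
        if traj.n_points < 2:
            continue
        any_ok = True
        sums, counts = _pair_sums(traj)
        for lag in np.flatnonzero(counts):
            lag = int(lag)
            per_lag.setdefault(lag, []).append(sums[lag] / counts[lag])
    if not any_ok:
        raise DomainError("TE-MSD needs at least one trajectory with >= 2 points")
    lags = np.array(sorted(per_lag), dtype=np.int64)
    values = np.array([np.mean(per_lag[n]) for n in lags])
    jn = np.array([len(per_lag[n]) for n in lags], dtype=np.int64)
    se = np.array(
        [
            np.std(per_lag[n], ddof=1) / np.sqrt(len(per_lag[n]))
            if len(per_lag[n]) > 1
            else np.nan
            for n in lags
        ]
    )
    return MSDCurve(lags, values, jn, set_.dt, TIME_ENSEMBLE_AVERAGED, se)


def fit_msd_linear(
    curve: MSDCurve,
    fraction: float = 0.25,
    min_points: int = 3,
    d: int = 2,
    R: float = 1.0 / 6.0,
) -> MSDFitResult:
    """Least-squares straight-line fit of the short-delay part of an MSD curve.

    The fit uses the ``max(min_points, ceil(fraction * n_max))`` shortest
    delays, where ``n_max`` is the number of points in the curve — the
    short-delay region is where the linear normal-diffusion model holds
    best and single-trajectory noise is smallest.  TE-MSD curves are fit
    with weights proportional to the per-delay trajectory count ``J_n``
    (long-delay points average few trajectories); T-MSD fits are
    unweighted.

    The slope gives ``D = slope / (2 d)``; for 2-D data the intercept
    ``4 (sigma^2 - 2 R D dt)`` is inverted for ``sigma`` when the result is
    non-negative.  Standard errors come from the fit covariance scaled by
    the residual variance.
    """
    if not 0 < fraction <= 1:
        raise DomainError(f"fraction must be in (0, 1], got {fraction}")
    if min_points < 3:
        raise DomainError("min_points must be >= 3")
    if len(curve) < min_points:
        raise FitError(
            f"curve has {len(curve)} points; need at least {min_points}"
        )
    m = max(min_points, math.ceil(fraction * len(curve)))
    m = min(m, len(curve))
    t = curve.delays[:m]
    y = curve.values[:m]
    if curve.kind == TIME_ENSEMBLE_AVERAGED:
        w = curve.counts[:m].astype(np.float64)
    else:
        w = np.ones(m)

    X = np.column_stack([t, np.ones(m)])
    XtW = X.T * w
    cov_unscaled = np.linalg.inv(XtW @ X)
    beta = cov_unscaled @ (XtW @ y)
    point_se = curve.se[:m] if curve.se is not None else None
    if point_se is not None and np.all(np.isfinite(point_se)):
        # propagate the per-delay uncertainty of the curve through the
        # weighted estimator: beta = A y with A = (X'WX)^-1 X'W
        A = cov_unscaled @ XtW
        cov = (A * point_se[None, :] ** 2) @ A.T
    else:
        resid = y - X @ beta
        dof = m - 2
        s2 = float((w * resid**2).sum() / dof) if dof > 0 else 0.0
        cov = cov_unscaled * s2
    slope, intercept = float(beta[0]), float(beta[1])
    se_slope = float(np.sqrt(max(cov[0, 0], 0.0)))
    se_intercept = float(np.sqrt(max(cov[1, 1], 0.0)))

    D = slope / (2 * d)
    se_D = se_slope / (2 * d)
    sigma2 = intercept / (2 * d) + 2 * R * D * curve.dt
    # tolerate rounding slightly below zero on exact noise-free curves
    tol = 1e-12 * float(np.max(np.abs(y))) / (2 * d)
    if sigma2 < 0 and sigma2 > -tol:
        sigma2 = 0.0
    sigma = float(np.sqrt(sigma2)) if sigma2 >= 0 else None
    return MSDFitResult(D, intercept, se_D, se_intercept, sigma, R, m, d)


def motion_blur_coefficient(
    shutter: Callable[[float], float],
    dt: float = 1.0,
    *,
    n_check: int = 2001,
) -> float:
    """Motion-blur coefficient ``R`` of a camera shutter profile.

    ``shutter`` is the normalized cumulative illumination profile
    ``S(tau)`` on ``[0, dt]``: the fraction of the frame's total exposure
    collected by time ``tau`` (monotone, 0 at the frame start, 1 at the
    end).  Then

        R = (1 / dt) * integral_0^dt S(tau) (1 - S(tau)) d tau

    evaluated by adaptive quadrature.  ``R`` lies in [0, 1/4]: 0 for an
    instantaneous exposure, 1/6 for a uniform full-frame exposure.
    """
    if dt <= 0:
        raise DomainError("dt must be positive")
    grid = np.linspace(0.0, dt, n_check)
    svals = np.array([shutter(float(tau)) for tau in grid])
    if np.any(np.diff(svals) < -1e-12) or not np.all(np.isfinite(svals)):
        raise DomainError("shutter profile must be monotone non-decreasing")
    if abs(svals[0]) > 1e-9 or abs(svals[-1] - 1.0) > 1e-9:
        raise DomainError("shutter profile must rise from 0 to 1 over the frame")
    val, _ = integrate.quad(
        lambda tau: shutter(tau) * (1.0 - shutter(tau)),
        0.0,
        dt,
        epsabs=1e-13,
        epsrel=1e-12,
        limit=500,
    )
    R = val / dt
    return float(min(max(R, 0.0), 0.25))


def uniform_exposure(t_exp: float, dt: float) -> Callable[[float], float]:
    """Cumulative shutter profile for a uniform exposure of length ``t_exp``
    starting at the beginning of a frame of length ``dt``."""
    if not 0 < t_exp <= dt:
        raise DomainError("need 0 < t_exp <= dt")

    def S(tau: float) -> float:
        return min(max(tau / t_exp, 0.0), 1.0)

    return S


def instantaneous_exposure(dt: float) -> Callable[[float], float]:
    """Cumulative shutter profile of an (idealized) instantaneous exposure
    at the start of the frame; gives ``R = 0``."""

    def S(tau: float) -> float:
        return 1.0 if tau > 0 else 0.0

    return S


def per_trajectory_D(
    set_: TrajectorySet,
    fraction: float = 0.25,
    min_points: int = 3,
    d: int = 2,
    R: float = 1.0 / 6.0,
) -> pd.DataFrame:
    """T-MSD fit of every trajectory in a set.

    Returns a DataFrame indexed by trajectory id with the fit fields of
    :class:`MSDFitResult` plus an ``error`` column; trajectories whose fit
    fails (too short, degenerate) get NaN estimates and the error message —
    failures are recorded, never raised.  Negative ``D`` estimates from
    noise-dominated tracks are retained.
    """
    rows = {}
    for traj in set_.trajectories:
        try:
            curve = t_msd(traj, set_.dt)
            fit = fit_msd_linear(curve, fraction, min_points, d, R)
            rows[traj.id] = {**fit.to_dict(), "error": ""}
        except (DomainError, FitError) as exc:
            rows[traj.id] = {
                "D": np.nan,
                "intercept": np.nan,
                "se_D": np.nan,
                "se_intercept": np.nan,
                "sigma": None,
                "R": R,
                "n_points_used": 0,
                "d": d,
                "error": str(exc),
            }
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "id"
    return df
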