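"""Survival-function analysis of squared displacements at fixed lag.

For free 2-D normal diffusion, the squared displacement ``r^2`` at delay
``t_n`` is exponentially distributed:

    1 - CDF(r^2, t_n) = exp(-r^2 / MSD(t_n))

so the empirical survival function is a straight line on a semi-log plot,
and its slope estimates the MSD at that delay.  Multiple decay rates reveal
a mixture of motion states — e.g. a small fraction of immobile steps hiding
inside a nominally mobile population — which is quantified here by
maximum-likelihood fitting of a 1- or 2-component exponential mixture via
expectation-maximization on the pooled ``r^2`` sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, FitError
from .trajectory_io import TrajectorySet

__all__ = [
    "SquaredDisplacementSample",
    "squared_displacements",
    "empirical_survival",
    "fit_exponential_mixture",
    "ExponentialMixtureFit",
]


@dataclass(frozen=True)
class SquaredDisplacementSample:
    """Pooled squared displacements at one frame lag."""

    lag: int
    values: np.ndarray  # r^2 samples, m^2
    population: str = ""

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 1 or len(values) == 0:
            raise DomainError("sample must be a non-empty 1-D array")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise DomainError("squared displacements must be finite and >= 0")
        if self.lag < 1:
            raise DomainError("lag must be >= 1")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return len(self.values)


def squared_displacements(
    set_: TrajectorySet, n: int = 1, population: str | None = None
) -> SquaredDisplacementSample:
    """Pool ``|x_{i+n} - x_i|^2`` over all trajectories at frame lag ``n``.

    Lags are frame-index differences, so gapped trajectories contribute
    only the pairs they actually span.  When ``population`` is given, only
    trajectories carrying that label are pooled.
    """
    if n < 1:
        raise DomainError("lag must be >= 1")
    vals: list[np.ndarray] = []
    for traj in set_.trajectories:
        if population is not None and set_.labels.get(traj.id) != population:
            continue
        if traj.n_points < 2:
            continue
        f = traj.frames
        # pairs exactly n frames apart, in frame-index terms
        pos = {int(fi): i for i, fi in enumerate(f)}
        idx = [(i, pos[int(fi) + n]) for i, fi in enumerate(f) if int(fi) + n in pos]
        if idx:
            a, b = zip(*idx)
            d = traj.coords[list(b)] - traj.coords[list(a)]
            vals.append((d**2).sum(axis=1))
    if not vals:
        raise DomainError(f"no displacement pair at lag {n}")
    return SquaredDisplacementSample(n, np.concatenate(vals), population or "")


def empirical_survival(
    sample: SquaredDisplacementSample,
) -> tuple[np.ndarray, np.ndarray]:
    """Empirical survival function ``1 - CDF`` of the ``r^2`` sample.

    Returns the sorted sample values and ``P(X > x)`` evaluated at each, a
    right-continuous step function starting below 1 and ending at 0.
    """
    x = np.sort(sample.values)
    n = len(x)
    # P(X > x_(i)) with ties sharing the survival of the last equal value
    surv = 1.0 - np.searchsorted(x, x, side="right") / n
    return x, surv


@dataclass(frozen=True)
class ExponentialMixtureFit:
    """MLE of a k-component exponential mixture on squared displacements.

    Components are sorted by scale ascending; ``scales`` are the component
    MSDs (m^2) and ``fractions`` sum to 1.
    """

    fractions: np.ndarray
    scales: np.ndarray
    log_likelihood: float
    n_iter: int
    converged: bool


def _em_exponential(
    x: np.ndarray, fractions: np.ndarray, scales: np.ndarray,
    max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, float, int, bool]:
    n = len(x)
    k = len(scales)
    ll_old = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: responsibilities under f(x) = sum_c pi_c exp(-x/s_c)/s_c
        logp = np.log(fractions)[None, :] - np.log(scales)[None, :] \
            - x[:, None] / scales[None, :]
        m = logp.max(axis=1, keepdims=True)
        p = np.exp(logp - m)
        tot = p.sum(axis=1, keepdims=True)
        resp = p / tot
        ll = float((np.log(tot[:, 0]) + m[:, 0]).sum())
        # M-step
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-300)
        fractions = nk / n
        scales = np.maximum((resp * x[:, None]).sum(axis=0) / nk, 1e-300)
        if abs(ll - ll_old) <= tol * (1.0 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll
    return fractions, scales, ll_old, it, converged


def fit_exponential_mixture(
    sample: SquaredDisplacementSample,
    k: int = 2,
    *,
    n_starts: int = 5,
    max_iter: int = 2000,
    tol: float = 1e-12,
    seed: int = 0,
) -> ExponentialMixtureFit:
    """Maximum-likelihood exponential-mixture fit of an ``r^2`` sample.

    ``k = 1`` reduces to the closed form ``scale = mean(r^2)``.  For
    ``k = 2`` the EM algorithm is run from ``n_starts`` seeded starting
    points (quantile-separated scales plus random perturbations) and the
    best-likelihood solution is returned.  Raises :class:`FitError`
    carrying the best iterate if no start converges within ``max_iter``.
    """
    if k not in (1, 2):
        raise DomainError("k must be 1 or 2")
    x = sample.values
    if len(x) < 10 * k:
        raise DomainError(f"need at least {10 * k} samples for k={k}")
    if k == 1:
        mean = float(x.mean())
        ll = float(-len(x) * (np.log(mean) + 1.0)) if mean > 0 else np.inf
        return ExponentialMixtureFit(
            np.array([1.0]), np.array([mean]), ll, 0, True
        )

    rng = np.random.default_rng(seed)
    mean = x.mean()
    # deterministic quantile-based start, then random perturbations
    q = np.quantile(x[x > 0], [0.1, 0.9]) if np.any(x > 0) else np.array([mean, mean])
    starts = [(np.array([0.5, 0.5]), np.maximum(q, 1e-300))]
    for _ in range(max(0, n_starts - 1)):
        f0 = rng.uniform(0.05, 0.95)
        s0 = mean * rng.lognormal(mean=-2.0, sigma=1.5)
        s1 = mean * rng.lognormal(mean=0.5, sigma=0.5)
        starts.append((np.array([f0, 1 - f0]), np.array([s0, s1])))

    best = None
    any_converged = False
    for f0, s0 in starts:
        f, s, ll, it, conv = _em_exponential(x, f0.copy(), s0.copy(), max_iter, tol)
        any_converged = any_converged or conv
        if best is None or ll > best[2]:
            best = (f, s, ll, it, conv)
    f, s, ll, it, conv = best
    order = np.argsort(s)
    fit = ExponentialMixtureFit(f[order], s[order], ll, it, conv)
    if not any_converged:
        raise FitError(f"EM did not converge in {max_iter} iterations; best: {fit}")
    return fit
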