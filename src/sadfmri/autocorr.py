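"""Autocorrelation-based self-labelling initialization.

A voxel with a hemodynamic response has a temporally structured series and
therefore a large sum of sample autocorrelations across short lags, while a
baseline voxel's series is close to white noise and sums to near 1 (the
lag-0 term). This contrast supplies the initial, automatically assigned
labels for semi-supervised training:

* ``sample_autocorr`` computes, per voxel,
  ``rho(i) = sum_k (x[k+i]-xbar)(x[k]-xbar) / (Var(x) * (T-i))``
  for lags ``i = 0..h_max`` (population 1/T variance, so ``rho(0) = 1``
  exactly), and the sum ``SA = sum_i rho(i)``.
* ``optimize_alpha`` picks the tail fraction ``alpha`` by minimising a
  trade-off between tail separation (a tail-value-at-risk contrast,
  normalised by the SA range) and the pool size penalty ``alpha``.
* ``assign_initial_labels`` labels the extreme upper/lower ``alpha/2``
  quantile tails 1 and 0 and balances class counts.
* ``check_confidence`` validates the pseudo-label confidence level ``c``
  against the SA distribution: ``-ln(1/c - 1) <= q_{1-alpha/2}(SA)``.
* ``adapt_hmax`` shrinks the lag count under downsampling,
  ``h_max -> ceil(h_max / d)``, to counteract the growing variance of SA
  (for white noise, Var(SA) scales like h_max / T).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np

from .preprocessing import TimeSeriesMatrix

__all__ = [
    "AutocorrResult",
    "InitPool",
    "DEFAULT_H_MAX",
    "ALPHA_GRID_MAX",
    "sample_autocorr",
    "optimize_alpha",
    "assign_initial_labels",
    "check_confidence",
    "adapt_hmax",
]

#: default maximal lag: 20 autocorrelation terms including lag 0
DEFAULT_H_MAX = 19
#: alpha grid upper bound; beyond 0.5 the two quantile tails would overlap
ALPHA_GRID_MAX = 0.5


@dataclasses.dataclass
class AutocorrResult:
    """Per-voxel autocorrelation profile and its sum.

    Attributes
    ----------
    rho : ndarray, shape (V, h_max + 1)
        Sample autocorrelation at lags 0..h_max; ``rho[:, 0] == 1``.
    SA : ndarray, shape (V,)
        Row sums of ``rho`` (lag 0 included).
    h_max : int
        Maximal lag used.
    """

    rho: np.ndarray
    SA: np.ndarray
    h_max: int


@dataclasses.dataclass
class InitPool:
    """Automatically labelled initialization pool (equal class counts)."""

    alpha: float
    q_low: float
    q_high: float
    members: list  # list of (voxel_id, label)
    objective_curve: list  # list of (alpha, J(alpha)); empty if alpha was fixed

    @property
    def voxel_ids(self) -> np.ndarray:
        return np.array([m[0] for m in self.members], dtype=int)

    @property
    def labels(self) -> np.ndarray:
        return np.array([m[1] for m in self.members], dtype=int)


def _as_values(m) -> np.ndarray:
    if isinstance(m, TimeSeriesMatrix):
        return m.values
    return np.atleast_2d(np.asarray(m, dtype=float))


def sample_autocorr(m, h_max: int = DEFAULT_H_MAX) -> AutocorrResult:
    """Sample autocorrelation at lags 0..h_max and its per-voxel sum.

    Uses the population (1/T) variance in the normaliser and divides the
    lag-i cross-sum by ``T - i``, which makes the lag-0 term exactly 1 for
    any non-constant row.
    """
    x = _as_values(m)
    v, t = x.shape
    if not 1 <= h_max <= t - 2:
        raise ValueError(f"h_max must satisfy 1 <= h_max <= T-2 = {t - 2}, got {h_max}")
    xc = x - x.mean(axis=1, keepdims=True)
    var = (xc ** 2).mean(axis=1)
    if (var <= 0).any():
        bad = np.flatnonzero(var <= 0).tolist()
        raise ValueError(f"constant time-series (zero variance) at rows {bad}")
    rho = np.empty((v, h_max + 1))
    for lag in range(h_max + 1):
        if lag == 0:
            num = (xc * xc).sum(axis=1)
        else:
            num = (xc[:, lag:] * xc[:, :-lag]).sum(axis=1)
        rho[:, lag] = num / (var * (t - lag))
    return AutocorrResult(rho=rho, SA=rho.sum(axis=1), h_max=h_max)


def _tail_objective(sa: np.ndarray, alpha: float) -> float:
    """Tail-value-at-risk contrast plus the tail-fraction penalty."""
    q_low = np.quantile(sa, alpha / 2.0)
    q_high = np.quantile(sa, 1.0 - alpha / 2.0)
    upper = sa[sa >= q_high]
    lower = sa[sa <= q_low]
    if upper.size == 0 or lower.size == 0:
        return math.inf
    spread = sa.max() - sa.min()
    return float((upper.mean() - lower.mean()) / spread + alpha)


def optimize_alpha(sa: np.ndarray, grid_step: float = 0.002):
    """Minimise the tail-separation/pool-size trade-off over an alpha grid.

    The objective is
    ``J(alpha) = (E[SA | SA >= q_{1-a/2}] - E[SA | SA <= q_{a/2}]) / range(SA) + alpha``
    with empirical (linear-interpolation) quantiles and empirical tail means.
    Grid: ``grid_step`` to 0.5 in steps of ``grid_step``; ties resolve to the
    smallest alpha. Returns ``(alpha, objective_curve)`` where the curve is a
    list of (alpha, J) pairs (infeasible grid points carry J = inf).
    """
    sa = np.asarray(sa, dtype=float).ravel()
    if len(np.unique(sa)) < 10:
        raise ValueError("need at least 10 distinct SA values to optimise alpha")
    if not 0 < grid_step <= 0.1:
        raise ValueError("grid_step must lie in (0, 0.1]")
    n_steps = int(round(ALPHA_GRID_MAX / grid_step))
    grid = np.arange(1, n_steps + 1) * grid_step
    grid = grid[grid <= ALPHA_GRID_MAX + 1e-12]
    curve = [(float(a), _tail_objective(sa, float(a))) for a in grid]
    finite = [(j, a) for a, j in curve if math.isfinite(j)]
    if not finite:
        raise ValueError("objective infeasible on the whole alpha grid")
    best_j = min(j for j, _ in finite)
    best_a = min(a for j, a in finite if j == best_j)
    return best_a, curve


def assign_initial_labels(sa: np.ndarray, alpha: float,
                          voxel_ids: np.ndarray | None = None,
                          objective_curve: list | None = None) -> InitPool:
    """Label the extreme SA tails: 1 above ``q_{1-alpha/2}``, 0 below ``q_{alpha/2}``.

    Strict inequalities at both thresholds; the larger class is truncated to
    the smaller one's size keeping the most extreme SA values, so the pool is
    exactly balanced.
    """
    sa = np.asarray(sa, dtype=float).ravel()
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if voxel_ids is None:
        voxel_ids = np.arange(sa.size)
    voxel_ids = np.asarray(voxel_ids)
    q_low = float(np.quantile(sa, alpha / 2.0))
    q_high = float(np.quantile(sa, 1.0 - alpha / 2.0))
    idx1 = np.flatnonzero(sa > q_high)
    idx0 = np.flatnonzero(sa < q_low)
    if idx1.size == 0 or idx0.size == 0:
        raise ValueError(
            f"initialization failure: empty tail at alpha={alpha} "
            f"(|C1|={idx1.size}, |C0|={idx0.size})")
    n = min(idx1.size, idx0.size)
    # keep most extreme values; break SA ties by voxel id for reproducibility
    order1 = idx1[np.lexsort((voxel_ids[idx1], -sa[idx1]))][:n]
    order0 = idx0[np.lexsort((voxel_ids[idx0], sa[idx0]))][:n]
    members = [(int(voxel_ids[i]), 0) for i in order0]
    members += [(int(voxel_ids[i]), 1) for i in order1]
    return InitPool(alpha=float(alpha), q_low=q_low, q_high=q_high,
                    members=members,
                    objective_curve=objective_curve if objective_curve else [])


def check_confidence(c: float, sa: np.ndarray, alpha: float) -> bool:
    """Whether confidence level ``c`` is compatible with the SA distribution.

    The pseudo-label gate ``P_NN / (1 + exp(-SA)) > c`` can only admit a
    voxel when its logistic factor exceeds ``c``, i.e. when
    ``SA > -ln(1/c - 1)``. The check requires that bound not to exceed the
    upper initialization quantile, so initialization-grade voxels remain
    admissible.
    """
    if not 0.5 < c < 1.0:
        raise ValueError("confidence level c must lie in (0.5, 1)")
    lhs = -math.log(1.0 / c - 1.0)
    q = float(np.quantile(np.asarray(sa, dtype=float), 1.0 - alpha / 2.0))
    return lhs <= q


def adapt_hmax(h_max: int, d: int) -> int:
    """Lag-count adaptation under downsampling: ``ceil(h_max / d)``."""
    if h_max < 1 or d < 1:
        raise ValueError("h_max and d must be >= 1")
    return -(-int(h_max) // int(d))
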