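"""GLM comparators: canonical HRF t-test, derivative F-test, FIR F-tests.

Three voxel-wise regression models serve as the conventional baseline
against which the sequence classifier is compared:

* ``t``      — Y = (h1, k) beta + e, a t-test on the canonical-HRF amplitude;
* ``fclass`` — Y = (h1, h2, h3, k) beta + e, an F-test over the canonical
  HRF plus its temporal and dispersion derivatives;
* ``fir10`` / ``fir20`` — a finite-impulse-response basis of 10 or 20
  contiguous boxcars spanning the window (plus intercept), F-test over all
  boxcars.

``h1`` is the conventional double-gamma HRF (response delay 6 s, undershoot
delay 16 s, unit dispersions, response/undershoot ratio 6, 32 s support),
peak-normalized. Family-wise error control across voxels uses a Bonferroni
threshold (a documented proxy for random-field-theory correction).
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import stats

__all__ = [
    "HrfBasis",
    "GlmStats",
    "GlmBatchResult",
    "canonical_hrf",
    "hrf_derivatives",
    "make_design",
    "fir_design",
    "fit_glm",
    "fit_glm_matrix",
    "fwer_threshold",
    "GLM_KINDS",
]

GLM_KINDS = ("t", "fclass", "fir10", "fir20")


@dataclasses.dataclass
class HrfBasis:
    """A design matrix with its provenance.

    ``columns`` is T x p with the intercept (all-ones) as the last column;
    the first ``n_test`` columns are the regressors under test. FIR boxcars
    tile the whole window and therefore sum to the intercept: that design is
    intentionally rank ``p - 1``; ``rank`` records the effective model rank
    and inference uses it (fitted values remain unique under the min-norm
    least-squares fit).
    """

    kind: str
    dt: float
    columns: np.ndarray
    n_test: int
    expected_rank: int | None = None

    def __post_init__(self):
        t, p = self.columns.shape
        if self.expected_rank is None:
            self.expected_rank = p
        self.rank = int(np.linalg.matrix_rank(self.columns))
        if self.rank < self.expected_rank:
            r = np.abs(np.diag(np.linalg.qr(self.columns, mode="r")))
            bad = np.flatnonzero(r < 1e-10 * r.max()).tolist()
            raise ValueError(
                f"design matrix for {self.kind} is rank deficient; "
                f"collinear columns {bad}")


@dataclasses.dataclass
class GlmStats:
    """Per-voxel fit summary for one comparator model."""

    kind: str
    beta: np.ndarray
    t: float | None
    F: float | None
    p_uncorrected: float
    residual_df: int
    threshold: float | None = None
    suprathreshold: bool | None = None

    @property
    def stat(self) -> float:
        return self.t if self.kind == "t" else self.F


@dataclasses.dataclass
class GlmBatchResult:
    """Vectorised fits of one design over many voxels."""

    kind: str
    beta: np.ndarray        # (V, p)
    stat: np.ndarray        # (V,) t or F values
    p_uncorrected: np.ndarray
    df_num: int             # q for F; 1 for t
    df_den: int
    threshold: float | None = None
    suprathreshold: np.ndarray | None = None


def canonical_hrf(dt: float, length: float = 32.0, peak_delay: float = 6.0,
                  undershoot_delay: float = 16.0, peak_disp: float = 1.0,
                  undershoot_disp: float = 1.0, ratio: float = 6.0,
                  onset: float = 0.0) -> np.ndarray:
    """Double-gamma HRF sampled at ``dt`` over ``length`` seconds, peak 1.

    Gamma shapes are delay/dispersion with scale = dispersion, so the
    response peaks near ``peak_delay`` seconds and the undershoot near
    ``undershoot_delay``; the undershoot is scaled down by ``ratio``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, length, dt) - onset
    tt = np.where(t < 0, 0.0, t)
    peak = stats.gamma.pdf(tt, peak_delay / peak_disp, scale=peak_disp)
    under = stats.gamma.pdf(tt, undershoot_delay / undershoot_disp,
                            scale=undershoot_disp)
    h = np.where(t < 0, 0.0, peak - under / ratio)
    m = np.abs(h).max()
    if m == 0:
        raise ValueError("degenerate HRF (all zero)")
    return h / m


def _orth(v: np.ndarray, against: np.ndarray) -> np.ndarray:
    return v - against * (against @ v) / (against @ against)


def hrf_derivatives(dt: float, onset_step: float = 1.0, disp_step: float = 0.01,
                    orthogonalize: bool = True, **hrf_kwargs):
    """Temporal and dispersion derivatives of the canonical HRF.

    ``h2`` is a finite difference w.r.t. onset (step ``onset_step`` s),
    ``h3`` w.r.t. the response dispersion (step ``disp_step``); both are
    sequentially orthogonalized against ``h1`` (and ``h2``) by default.
    """
    if onset_step == 0 or disp_step == 0:
        raise ValueError("degenerate basis: perturbation steps must be nonzero")
    h1 = canonical_hrf(dt, **hrf_kwargs)
    h_shift = canonical_hrf(dt, onset=onset_step, **hrf_kwargs)
    h2 = (h1 - h_shift) / onset_step
    disp = hrf_kwargs.get("peak_disp", 1.0)
    kw = dict(hrf_kwargs)
    kw["peak_disp"] = disp + disp_step
    h_disp = canonical_hrf(dt, **kw)
    h3 = (h1 - h_disp) / disp_step
    if np.allclose(h2, 0) or np.allclose(h3, 0):
        raise ValueError("degenerate basis: derivative column is zero")
    if orthogonalize:
        h2 = _orth(h2, h1)
        h3 = _orth(_orth(h3, h1), h2)
    return h2, h3


def _hrf_regressor(t_samples: int, dt: float, onset: float = 0.0,
                   **kwargs) -> np.ndarray:
    """Canonical HRF laid onto a T-sample stimulus-locked window."""
    h = canonical_hrf(dt, onset=onset, **kwargs)
    col = np.zeros(t_samples)
    n = min(t_samples, h.size)
    col[:n] = h[:n]
    return col


def fir_design(t_samples: int, dt: float, n_box: int) -> np.ndarray:
    """FIR boxcar design: ``n_box`` contiguous indicators plus intercept.

    Column j (1-based) is the indicator of samples with
    ``(j-1) w <= t dt < j w`` where ``w = T dt / n_box``.
    """
    if n_box >= t_samples:
        raise ValueError(f"n_box={n_box} >= T={t_samples}: rank deficient")
    # box index of sample t is floor(t*dt / w) = floor(t*n_box / T); the
    # integer form avoids float boundary wobble at exact box edges
    idx = (np.arange(t_samples) * n_box) // t_samples
    cols = np.zeros((t_samples, n_box))
    cols[np.arange(t_samples), idx] = 1.0
    return np.column_stack([cols, np.ones(t_samples)])


def make_design(kind: str, t_samples: int, dt: float, onset: float = 0.0,
                orthogonalize: bool = True) -> HrfBasis:
    """Build the design matrix for one of the comparator models."""
    if kind == "t":
        h1 = _hrf_regressor(t_samples, dt, onset)
        cols = np.column_stack([h1, np.ones(t_samples)])
        n_test = 1
    elif kind == "fclass":
        h1 = _hrf_regressor(t_samples, dt, onset)
        h2, h3 = hrf_derivatives(dt, orthogonalize=orthogonalize)

        def lay(h):
            col = np.zeros(t_samples)
            n = min(t_samples, h.size)
            col[:n] = h[:n]
            return col

        cols = np.column_stack([h1, lay(h2), lay(h3), np.ones(t_samples)])
        n_test = 3
    elif kind in ("fir10", "fir20"):
        n_box = 10 if kind == "fir10" else 20
        cols = fir_design(t_samples, dt, n_box)
        # boxcars partition the window, so intercept is in their span
        return HrfBasis(kind=kind, dt=dt, columns=cols, n_test=n_box,
                        expected_rank=n_box)
    else:
        raise ValueError(f"unknown model kind {kind!r}; choose from {GLM_KINDS}")
    return HrfBasis(kind=kind, dt=dt, columns=cols, n_test=n_test)


def fit_glm_matrix(Y: np.ndarray, design: HrfBasis) -> GlmBatchResult:
    """Ordinary least squares of every row of Y (V, T) on the design.

    For the ``t`` model the statistic is ``beta_1 / se(beta_1)`` with a
    two-sided p-value; otherwise the classical F-test of the model against
    the intercept-only reduction, upper-tail p, with numerator df equal to
    the effective model rank minus one (for the full-rank canonical designs
    this is exactly the number of non-intercept regressors; for the FIR
    designs, whose boxcars tile the window, it is ``n_box - 1``).
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    X = design.columns
    t_len, p = X.shape
    if Y.shape[1] != t_len:
        raise ValueError("series length does not match the design")
    rank = design.rank
    if t_len <= rank:
        raise ValueError(f"T={t_len} <= rank={rank}: no residual degrees of freedom")
    beta, *_ = np.linalg.lstsq(X, Y.T, rcond=None)  # (p, V), min-norm if singular
    resid = Y.T - X @ beta
    rss = (resid ** 2).sum(axis=0)
    df_den = t_len - rank
    sigma2 = rss / df_den
    with np.errstate(divide="ignore", invalid="ignore"):
        if design.kind == "t":
            xtx_inv = np.linalg.inv(X.T @ X)
            se = np.sqrt(sigma2 * xtx_inv[0, 0])
            stat = beta[0] / se
            p_unc = 2.0 * stats.t.sf(np.abs(stat), df_den)
            df_num = 1
        else:
            ones = np.ones((t_len, 1))
            beta0, *_ = np.linalg.lstsq(ones, Y.T, rcond=None)
            rss0 = ((Y.T - ones @ beta0) ** 2).sum(axis=0)
            q = rank - 1
            stat = ((rss0 - rss) / q) / sigma2
            stat = np.maximum(stat, 0.0)
            p_unc = stats.f.sf(stat, q, df_den)
            df_num = q
    return GlmBatchResult(kind=design.kind, beta=beta.T, stat=stat,
                          p_uncorrected=p_unc, df_num=df_num, df_den=df_den)


def fit_glm(y: np.ndarray, design: HrfBasis) -> GlmStats:
    """Fit one series; see :func:`fit_glm_matrix`."""
    res = fit_glm_matrix(np.asarray(y, dtype=float)[None, :], design)
    is_t = design.kind == "t"
    return GlmStats(kind=design.kind, beta=res.beta[0],
                    t=float(res.stat[0]) if is_t else None,
                    F=None if is_t else float(res.stat[0]),
                    p_uncorrected=float(res.p_uncorrected[0]),
                    residual_df=res.df_den)


def fwer_threshold(result: GlmBatchResult, alpha: float = 0.05,
                   method: str = "bonferroni") -> GlmBatchResult:
    """Family-wise error control across voxels via Bonferroni.

    Sets ``threshold`` (the critical statistic value) and per-voxel
    ``suprathreshold`` flags on the batch result. With a single voxel this
    reduces to the ordinary uncorrected critical value.
    """
    if method != "bonferroni":
        raise ValueError("only the Bonferroni method is implemented")
    m = result.stat.size
    if m < 1:
        raise ValueError("need at least one voxel")
    a = alpha / m
    if result.kind == "t":
        crit = float(stats.t.ppf(1.0 - a / 2.0, result.df_den))
        flags = np.abs(result.stat) > crit
    else:
        crit = float(stats.f.ppf(1.0 - a, result.df_num, result.df_den))
        flags = result.stat > crit
    result.threshold = crit
    result.suprathreshold = flags
    return result
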