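import math

import numpy as np
import pytest
from scipy.stats import spearmanr

from sadfmri import (sample_autocorr, optimize_alpha, assign_initial_labels,
                     check_confidence, adapt_hmax)
from sadfmri.autocorr import _tail_objective


def slow_autocorr_sum(x, h_max):
    """Independent double-loop oracle for the summed sample autocorrelation."""
    x = np.asarray(x, dtype=float)
    t = x.size
    xbar = x.mean()
    var = np.mean((x - xbar) ** 2)
    sa = 0.0
    rho = []
    for i in range(h_max + 1):
        acc = 0.0
        for k in range(t - i):
            acc += (x[k + i] - xbar) * (x[k] - xbar)
        r = acc / (var * (t - i))
        rho.append(r)
        sa += r
    return np.array(rho), sa


class TestSampleAutocorr:
    def test_lag_zero_is_one(self, rng):
        res = sample_autocorr(rng.standard_normal((20, 50)), h_max=10)
        np.testing.assert_allclose(res.rho[:, 0], 1.0, atol=1e-10)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(50):
            t = int(rng.integers(25, 70))
            h = int(min(19, t - 2))
            x = rng.standard_normal(t) + rng.uniform(-2, 2)
            res = sample_autocorr(x[None, :], h_max=h)
            rho, sa = slow_autocorr_sum(x, h)
            np.testing.assert_allclose(res.rho[0], rho, atol=1e-10)
            assert abs(res.SA[0] - sa) < 1e-10

    def test_alternating_row(self):
        x = np.tile([1.0, -1.0], 140)  # T = 280
        res = sample_autocorr(x[None, :], h_max=3)
        rho, sa = slow_autocorr_sum(x, 3)
        np.testing.assert_allclose(res.rho[0], rho, atol=1e-12)
        # with population variance 1 the (T-i) normalisation gives exactly -/+1
        assert res.rho[0, 1] == pytest.approx(-1.0)
        assert res.rho[0, 2] == pytest.approx(1.0)

    def test_white_noise_mean_sa_matches_monte_carlo_oracle(self):
        t, h = 280, 19
        impl = sample_autocorr(
            np.random.default_rng(1).standard_normal((10_000, t)), h_max=h).SA
        # independent oracle: per-lag sums via correlate on fresh draws
        rng = np.random.default_rng(2)
        oracle = []
        for _ in range(2_000):
            x = rng.standard_normal(t)
            xc = x - x.mean()
            full = np.correlate(xc, xc, mode="full")[t - 1:t + h]
            denom = xc.var() * (t - np.arange(h + 1))
            oracle.append(np.sum(full / denom))
        oracle = np.asarray(oracle)
        se = math.hypot(impl.std() / math.sqrt(impl.size),
                        oracle.std() / math.sqrt(oracle.size))
        assert abs(impl.mean() - oracle.mean()) < 3 * se
        # near 1, the signature of a temporally random signal
        assert 0.7 < impl.mean() < 1.1

    def test_affine_invariance(self, rng):
        x = rng.standard_normal((5, 60))
        a = sample_autocorr(x, 10).SA
        b = sample_autocorr(3.7 * x - 11.0, 10).SA
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_variance_grows_with_hmax_over_T(self):
        rng = np.random.default_rng(7)
        ratios, variances = [], []
        for t in (40, 80, 160, 280):
            for h in (4, 9, 19):
                sa = sample_autocorr(rng.standard_normal((500, t)), h_max=h).SA
                ratios.append(h / t)
                variances.append(sa.var())
        rho, _ = spearmanr(ratios, variances)
        assert rho > 0.9

    def test_constant_row_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            sample_autocorr(np.ones((1, 30)), h_max=5)

    def test_hmax_out_of_range(self, rng):
        with pytest.raises(ValueError, match="h_max"):
            sample_autocorr(rng.standard_normal((1, 10)), h_max=9)


def brute_force_alpha(sa, grid_step=0.002):
    """Exhaustive re-evaluation of the tail-trade-off objective."""
    best_a, best_j = None, np.inf
    n = int(round(0.5 / grid_step))
    for i in range(1, n + 1):
        a = i * grid_step
        ql, qh = np.quantile(sa, [a / 2, 1 - a / 2])
        up, lo = sa[sa >= qh], sa[sa <= ql]
        if up.size == 0 or lo.size == 0:
            continue
        j = (up.mean() - lo.mean()) / (sa.max() - sa.min()) + a
        if j < best_j - 1e-15:
            best_j, best_a = j, a
    return best_a


class TestOptimizeAlpha:
    def test_matches_bruteforce_on_random_samples(self, rng):
        for _ in range(20):
            kind = rng.integers(3)
            n = int(rng.integers(200, 1200))
            if kind == 0:
                sa = rng.normal(1, 0.3, n)
            elif kind == 1:
                sa = np.concatenate([rng.normal(0.9, 0.05, int(0.95 * n)),
                                     rng.normal(8, 0.5, n - int(0.95 * n))])
            else:
                sa = rng.gamma(2.0, 1.0, n)
            alpha, _ = optimize_alpha(sa)
            assert alpha == pytest.approx(brute_force_alpha(sa))

    def test_mixture_example(self):
        rng = np.random.default_rng(42)
        sa = np.concatenate([rng.normal(0.9, 0.05, 950), rng.normal(8, 0.5, 50)])
        alpha, curve = optimize_alpha(sa)
        assert alpha == pytest.approx(brute_force_alpha(sa))
        assert len(curve) == 250

    def test_tail_separation_non_increasing_in_alpha(self, rng):
        grid = np.arange(1, 251) * 0.002
        for _ in range(20):
            sa = rng.normal(size=300) * rng.uniform(0.5, 3) + rng.uniform(-1, 5)
            sep = [_tail_objective(sa, a) - a for a in grid]
            assert all(s1 >= s2 - 1e-12 for s1, s2 in zip(sep, sep[1:]))

    def test_no_class_structure_prefers_smallest_alpha(self, rng):
        # bounded jitter with no tail structure: the separation term falls
        # slower than the +alpha penalty rises, so the smallest grid alpha wins
        sa = 1.0 + 1e-6 * rng.uniform(0, 1, 500)
        alpha, _ = optimize_alpha(sa)
        assert alpha == pytest.approx(0.002)
        assert alpha == pytest.approx(brute_force_alpha(sa))

    def test_too_few_distinct_values_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            optimize_alpha(np.array([1.0, 2.0] * 20))


class TestAssignInitialLabels:
    def test_integer_ramp_quantile_arithmetic(self):
        sa = np.arange(1.0, 101.0)
        pool = assign_initial_labels(sa, 0.10)
        assert pool.q_low == pytest.approx(np.quantile(sa, 0.05))
        assert pool.q_high == pytest.approx(np.quantile(sa, 0.95))
        lab0 = sorted(v for v, l in pool.members if l == 0)
        lab1 = sorted(v for v, l in pool.members if l == 1)
        # values 1..5 sit strictly below q_0.05 = 5.95; 96..100 above q_0.95
        assert sa[lab0].tolist() == [1, 2, 3, 4, 5]
        assert sa[lab1].tolist() == [96, 97, 98, 99, 100]

    def test_classes_balanced_and_extreme(self, rng):
        sa = rng.gamma(1.5, 2.0, 400)  # right-skewed: unequal raw tails
        pool = assign_initial_labels(sa, 0.2)
        lab0 = [v for v, l in pool.members if l == 0]
        lab1 = [v for v, l in pool.members if l == 1]
        assert len(lab0) == len(lab1) > 0
        assert set(lab0).isdisjoint(lab1)
        assert all(sa[v] < pool.q_low for v in lab0)
        assert all(sa[v] > pool.q_high for v in lab1)
        # truncation keeps the most extreme values of the larger tail
        raw1 = np.flatnonzero(sa > pool.q_high)
        kept = np.sort(sa[lab1])
        assert np.all(kept >= np.sort(sa[raw1])[-len(lab1):][0])

    def test_empty_tail_is_initialization_failure(self):
        sa = np.array([1.0, 2.0, 3.0, 5.0, 5.0, 5.0, 5.0, 5.0])
        with pytest.raises(ValueError, match="initialization failure"):
            assign_initial_labels(sa, 0.05)


class TestConfidenceAndLags:
    def test_confidence_bound_closed_form(self, rng):
        sa = rng.normal(1, 0.5, 1000)
        q95 = np.quantile(sa, 0.975)
        # c = 0.98 -> lhs = ln 49 = 3.8918, far above this sample's quantile
        assert math.isclose(-math.log(1 / 0.98 - 1), math.log(49))
        assert check_confidence(0.98, sa, 0.05) == (math.log(49) <= q95)
        assert not check_confidence(0.98, sa, 0.05)
        assert check_confidence(0.501, sa, 0.05)      # lhs ~ 0
        assert not check_confidence(1 - 1e-9, sa, 0.05)  # lhs -> inf

    def test_confidence_outside_range_rejected(self):
        with pytest.raises(ValueError):
            check_confidence(0.4, np.ones(10), 0.05)

    @pytest.mark.parametrize("h,d,expected", [(19, 2, 10), (19, 5, 4),
                                              (19, 1, 19), (19, 10, 2), (1, 7, 1)])
    def test_adapt_hmax_ceiling(self, h, d, expected):
        assert adapt_hmax(h, d) == expected
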