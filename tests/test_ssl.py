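import math

import numpy as np
import pytest
from scipy.special import expit
from sklearn.base import clone

import sadfmri as sf
from sadfmri import (TrainConfig, SadClassifier, regularized_score,
                     pseudo_label_round, run_sad, predict)


class StubModel:
    """Duck-typed stand-in emitting preset network probabilities."""

    def __init__(self, probs):
        self.probs = np.asarray(probs, dtype=float)

    def predict_proba(self, X):
        return self.probs[: len(X)]


class TestRegularizedScore:
    def test_closed_forms(self):
        assert regularized_score(np.array([0.9]), np.array([0.0]))[0] == pytest.approx(0.45)
        # SA = ln 49 makes the logistic factor 49/50, the c = 0.98 crossing
        got = regularized_score(np.array([0.99]), np.array([math.log(49)]))[0]
        assert got == pytest.approx(0.99 * 49 / 50, abs=1e-12)
        # saturation for very large SA
        assert regularized_score(np.array([0.99]), np.array([1e4]))[0] == pytest.approx(0.99)
        assert regularized_score(np.array([0.99]), np.array([-1e4]))[0] == pytest.approx(0.0, abs=1e-12)

    def test_strictly_below_network_probability(self, rng):
        p = rng.uniform(0.01, 0.99, 100)
        sa = rng.uniform(-20, 20, 100)
        assert np.all(regularized_score(p, sa) < p)

    def test_monotone_in_sa_tightens_class1_gate(self):
        sa = np.linspace(-5, 10, 50)
        scores = regularized_score(np.full(50, 0.99), sa)
        assert np.all(np.diff(scores) > 0)  # lower SA -> harder to pass any c

    def test_eq5_compatible_confidence_admits_init_tail(self, rng):
        # when the confidence bound holds, every SA above the upper quantile
        # has a logistic factor exceeding c
        sa = np.concatenate([rng.normal(1, 0.3, 900), rng.normal(8, 1.0, 100)])
        alpha, c = 0.1, 0.98
        assert sf.check_confidence(c, sa, alpha)
        q = np.quantile(sa, 1 - alpha / 2)
        assert np.all(expit(sa[sa > q]) > c)


class TestPseudoLabelRound:
    def _config(self, per_class_add=500):
        return TrainConfig(per_class_add=per_class_add, allow_unsafe_confidence=True)

    def test_caps_additions_at_per_class_limit(self, rng):
        probs = np.r_[rng.uniform(0.985, 1.0, 700), rng.uniform(0.4, 0.6, 300)]
        sa = np.full(1000, 1e3)  # logistic factor 1: P_pred == P_NN
        ids = np.arange(1000)
        rnd = pseudo_label_round(StubModel(probs), np.zeros((1000, 4)), ids, sa,
                                 self._config())
        assert len(rnd.added_1) == 500 and not rnd.stopped
        top500 = set(np.argsort(-probs)[:500].tolist())
        assert set(rnd.added_1) == top500

    def test_fewer_candidates_than_cap_triggers_stop(self, rng):
        probs = np.r_[rng.uniform(0.985, 1.0, 300), rng.uniform(0.3, 0.7, 700)]
        sa = np.full(1000, 1e3)
        rnd = pseudo_label_round(StubModel(probs), np.zeros((1000, 4)),
                                 np.arange(1000), sa, self._config())
        assert len(rnd.added_1) == 300 and rnd.stopped
        assert "300" in rnd.reason

    def test_exact_threshold_excluded(self):
        # c = 0.75 is exactly representable, so P_pred == c and == 1-c are
        # genuine boundary cases
        probs = np.array([0.75, 0.8, 0.25, 0.2])
        sa = np.full(4, 1e3)
        cfg = TrainConfig(c=0.75, per_class_add=4, allow_unsafe_confidence=True)
        rnd = pseudo_label_round(StubModel(probs), np.zeros((4, 3)),
                                 np.arange(4), sa, cfg)
        assert rnd.added_1 == [1]   # P_pred == c excluded (strict >)
        assert rnd.added_0 == [3]   # P_pred == 1-c excluded (strict <)

    def test_ties_break_on_voxel_id(self):
        probs = np.array([0.99, 0.99, 0.99, 0.99])
        sa = np.full(4, 1e3)
        rnd = pseudo_label_round(StubModel(probs), np.zeros((4, 3)),
                                 np.array([7, 3, 9, 5]), sa, self._config(per_class_add=2))
        assert rnd.added_1 == [3, 5]

    def test_missing_model_is_state_error(self):
        with pytest.raises(RuntimeError):
            pseudo_label_round(None, np.zeros((2, 3)), np.arange(2),
                               np.ones(2), self._config())


class TestRunSad:
    def test_confidence_gate_refuses_incompatible_c(self):
        data = sf.generate(sf.SyntheticSpec(n_active=30, n_baseline=270,
                                            amplitude_pct=0.3, seed=3))
        cfg = TrainConfig(seed=0, max_iterations=1, epochs=1)
        with pytest.raises(ValueError, match="confidence"):
            run_sad(data.series, cfg)

    def test_max_iterations_one_trains_on_init_pool_only(self):
        data = sf.generate(sf.SyntheticSpec(n_active=40, n_baseline=360, seed=4))
        cfg = TrainConfig(seed=0, max_iterations=1, epochs=2, alpha=0.1,
                          allow_unsafe_confidence=True)
        res = run_sad(data.series, cfg)
        assert res.n_iterations == 1 and len(res.val_losses) == 1
        np.testing.assert_array_equal(np.sort(res.pool_ids),
                                      np.sort(res.init_pool.voxel_ids))

    def test_pool_grows_monotonically_without_relabelling(self):
        data = sf.generate(sf.SyntheticSpec(n_active=60, n_baseline=540,
                                            amplitude_pct=2.0, seed=7))
        cfg = TrainConfig(seed=3, max_iterations=3, epochs=8, per_class_add=10,
                          alpha=0.1, allow_unsafe_confidence=True)
        res = run_sad(data.series, cfg)
        assert len(np.unique(res.pool_ids)) == len(res.pool_ids)
        init = set(int(i) for i in res.init_pool.voxel_ids)
        assert init <= set(int(i) for i in res.pool_ids)
        seen = set(init)
        for rnd in res.rounds:
            new = set(rnd.added_0) | set(rnd.added_1)
            assert new.isdisjoint(seen)
            seen |= new

    def test_recovery_on_well_separated_classes(self, separable_training_run):
        """Full-loop recovery: pure class-1 pool and high accuracy (3 seeds)."""
        data, cfg, first = separable_training_run
        accs, purities = [], []
        for seed, res in [(cfg.seed, first)] + [
                (s, run_sad(data.series,
                            sf.TrainConfig(**{**cfg.__dict__, "seed": s})))
                for s in (1, 2)]:
            purity = data.truth[res.pool_ids[res.pool_labels == 1]].mean()
            _, _, cls = predict(res.model, data.series, h_max=cfg.h_max)
            accs.append((cls == data.truth).mean())
            purities.append(purity)
        assert min(purities) >= 0.90
        assert min(accs) >= 0.95

    def test_validation_losses_finite_and_best_checkpoint_selected(self, separable_training_run):
        _, _, res = separable_training_run
        assert np.all(np.isfinite(res.val_losses))
        assert res.best_iteration == int(np.argmin(res.val_losses)) + 1


class TestPredict:
    def test_threshold_rules(self):
        net = sf.BiLstmNet(seed=0)
        x = np.random.default_rng(0).standard_normal((5, 30))
        p_nn, p_pred, cls = predict(net, x, threshold=1.0)
        assert np.all(cls == 0)
        np.testing.assert_array_equal(cls, (p_pred > 1.0).astype(int))
        _, p_pred, cls = predict(net, x, threshold=0.0)
        assert np.all(cls == (p_pred > 0).astype(int))
        assert np.all(p_pred < p_nn)


class TestSadClassifierEstimator:
    def test_sklearn_protocol(self):
        clf = SadClassifier(epochs=2, max_iterations=1, alpha=0.2,
                            allow_unsafe_confidence=True, random_state=0)
        params = clf.get_params()
        assert params["epochs"] == 2 and params["c"] == 0.98
        cloned = clone(clf)
        assert cloned.get_params() == params
        clf.set_params(threshold=0.4)
        assert clf.threshold == 0.4

    def test_fit_predict_roundtrip(self):
        data = sf.generate(sf.SyntheticSpec(n_active=40, n_baseline=360,
                                            amplitude_pct=2.0, seed=9))
        clf = SadClassifier(epochs=4, max_iterations=1, alpha=0.15,
                            allow_unsafe_confidence=True, random_state=0)
        clf.fit(data.series.values)
        assert hasattr(clf, "model_") and clf.n_iter_ == 1
        proba = clf.predict_proba(data.series.values)
        assert proba.shape == (400, 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        pred = clf.predict(data.series.values)
        np.testing.assert_array_equal(pred, (proba[:, 1] > 0.5).astype(int))

    def test_unfitted_predict_raises(self):
        with pytest.raises(RuntimeError, match="not fitted"):
            SadClassifier().predict(np.zeros((3, 10)))
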