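"""Iterative semi-supervised training loop and the SadClassifier estimator.

The loop starts from the autocorrelation-labelled initialization pool, trains
the Bi-LSTM for a fixed number of epochs, then pseudo-labels unseen voxels
with the SA-regularized score

    P_pred(x_v) = P_NN(x_v) / (1 + exp(-SA_v)),

keeps only predictions above the confidence level ``c`` (class 1,
``P_pred > c``) or below ``1 - c`` (class 0), adds the ``per_class_add``
most extreme per class to the pool, and repeats. The logistic factor makes
class-1 assignment strictly harder for voxels with low temporal
autocorrelation, countering the class imbalance of real fMRI data. Training
stops when a round contributes fewer than ``per_class_add`` class-1 labels
or when ``max_iterations`` is reached; the returned model is the checkpoint
with the lowest validation loss across iterations. Newly added samples are
split 70/30 into train/validation at the moment they are added, and those
splits are frozen thereafter.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator

from . import autocorr as ac
from .network import BiLstmNet, SadNetworkSpec, fit_epochs
from .preprocessing import TimeSeriesMatrix, standardize

__all__ = [
    "TrainConfig",
    "PseudoLabelRound",
    "SadResult",
    "SadClassifier",
    "regularized_score",
    "pseudo_label_round",
    "run_sad",
    "predict",
]


@dataclasses.dataclass
class TrainConfig:
    """Hyperparameters of the semi-supervised loop."""

    c: float = 0.98
    per_class_add: int = 500
    max_iterations: int = 20
    split: float = 0.70
    epochs: int = 50
    batch_size: int = 32
    lr: float = 1e-3
    seed: int = 0
    final_threshold: float = 0.5
    h_max: int = ac.DEFAULT_H_MAX
    alpha: float | None = None  # None -> optimised on the SA sample
    grid_step: float = 0.002
    warm_start: bool = True
    allow_unsafe_confidence: bool = False

    def __post_init__(self):
        if not 0.0 < self.split < 1.0:
            raise ValueError("split must lie in (0, 1)")
        if not 0.5 < self.c < 1.0:
            raise ValueError("confidence level c must lie in (0.5, 1)")


@dataclasses.dataclass
class PseudoLabelRound:
    """Outcome of one pseudo-labelling round."""

    iteration: int
    candidates: list  # (voxel_id, P_NN, P_pred, label or None)
    added_0: list
    added_1: list
    stopped: bool
    reason: str = ""


@dataclasses.dataclass
class SadResult:
    """Everything the semi-supervised loop produced."""

    model: BiLstmNet
    init_pool: ac.InitPool
    rounds: list  # PseudoLabelRound history
    pool_ids: np.ndarray
    pool_labels: np.ndarray
    val_losses: list
    best_iteration: int
    n_iterations: int
    alpha: float
    sa: np.ndarray


def regularized_score(p_nn: np.ndarray, sa: np.ndarray) -> np.ndarray:
    """SA-shrunk activation score ``P_NN / (1 + exp(-SA))``.

    Equals ``P_NN * logistic(SA)``; saturates cleanly for extreme SA.
    Strictly smaller than ``P_NN`` for every finite SA.
    """
    p_nn = np.asarray(p_nn, dtype=float)
    sa = np.asarray(sa, dtype=float)
    if p_nn.shape != sa.shape:
        raise ValueError("P_NN and SA must have equal length")
    return p_nn * expit(sa)


def pseudo_label_round(model: BiLstmNet, X_unlab: np.ndarray, ids: np.ndarray,
                       sa: np.ndarray, config: TrainConfig,
                       iteration: int = 0) -> PseudoLabelRound:
    """Score unseen voxels and pick confident pseudo-labels.

    Class 1: ``P_pred > c`` strictly, the ``per_class_add`` highest scores;
    class 0: ``P_pred < 1 - c`` strictly, the ``per_class_add`` lowest.
    Ties break on voxel id. The round is flagged as stopping when fewer than
    ``per_class_add`` class-1 labels qualify.
    """
    if model is None:
        raise RuntimeError("no trained model available for pseudo-labelling")
    if len(X_unlab) == 0:
        return PseudoLabelRound(iteration, [], [], [], True, "no unlabelled voxels")
    p_nn = model.predict_proba(X_unlab)
    p_pred = regularized_score(p_nn, sa)
    k = config.per_class_add
    hi = np.flatnonzero(p_pred > config.c)
    lo = np.flatnonzero(p_pred < 1.0 - config.c)
    hi = hi[np.lexsort((ids[hi], -p_pred[hi]))][:k]
    lo = lo[np.lexsort((ids[lo], p_pred[lo]))][:k]
    label = {int(ids[i]): 1 for i in hi}
    label.update({int(ids[i]): 0 for i in lo})
    candidates = [(int(ids[i]), float(p_nn[i]), float(p_pred[i]),
                   label.get(int(ids[i])))
                  for i in range(len(ids))]
    stopped = len(hi) < k
    reason = f"round added {len(hi)} < {k} class-1 labels" if stopped else ""
    return PseudoLabelRound(iteration, candidates,
                            [int(ids[i]) for i in lo], [int(ids[i]) for i in hi],
                            stopped, reason)


def _split_new(ids: np.ndarray, labels: np.ndarray, split: float, rng):
    """Random 70/30 split of newly added samples (frozen afterwards)."""
    perm = rng.permutation(len(ids))
    n_train = int(round(split * len(ids)))
    if len(ids) > 1:
        n_train = min(max(n_train, 1), len(ids) - 1)
    tr, va = perm[:n_train], perm[n_train:]
    return ids[tr], labels[tr], ids[va], labels[va]


def run_sad(data: TimeSeriesMatrix | np.ndarray, config: TrainConfig = TrainConfig(),
            spec: SadNetworkSpec | None = None) -> SadResult:
    """Execute the full semi-supervised loop on one dataset.

    ``data`` rows are standardized if not already; SA is computed with
    ``config.h_max`` lags, alpha optimised (unless fixed), the tails
    labelled, and the Bi-LSTM trained iteratively with pseudo-label
    expansion. Returns the lowest-validation-loss checkpoint and the full
    pool history.
    """
    if isinstance(data, np.ndarray):
        data = TimeSeriesMatrix(values=data, dt=1.0)
    if data.units != "standardized":
        data = standardize(data)
    X = data.values
    ids = np.asarray(data.voxel_ids)
    res = ac.sample_autocorr(X, config.h_max)
    sa = res.SA
    if config.alpha is None:
        alpha, curve = ac.optimize_alpha(sa, config.grid_step)
    else:
        alpha, curve = float(config.alpha), []
    if not ac.check_confidence(config.c, sa, alpha) and not config.allow_unsafe_confidence:
        raise ValueError(
            f"confidence level c={config.c} violates the SA-quantile bound; "
            "lower c or set allow_unsafe_confidence=True")
    init_pool = ac.assign_initial_labels(sa, alpha, voxel_ids=ids,
                                         objective_curve=curve)

    id_to_row = {int(v): i for i, v in enumerate(ids)}
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17]))
    pool_ids = init_pool.voxel_ids
    pool_labels = init_pool.labels
    tr_ids, tr_y, va_ids, va_y = _split_new(pool_ids, pool_labels, config.split, rng)
    labelled = set(int(i) for i in pool_ids)

    model = BiLstmNet(spec, seed=config.seed)
    rounds: list[PseudoLabelRound] = []
    val_losses: list[float] = []
    checkpoints: list[BiLstmNet] = []
    stop_reason = "max_iterations reached"
    n_iter = 0
    for it in range(1, config.max_iterations + 1):
        n_iter = it
        if not config.warm_start and it > 1:
            model = BiLstmNet(spec, seed=config.seed)
        rows_tr = np.array([id_to_row[int(i)] for i in tr_ids])
        rows_va = np.array([id_to_row[int(i)] for i in va_ids])
        hist = fit_epochs(model, X[rows_tr], tr_y,
                          X_val=X[rows_va] if rows_va.size else None,
                          y_val=va_y if rows_va.size else None,
                          epochs=config.epochs, batch_size=config.batch_size,
                          lr=config.lr, seed=config.seed + it)
        val = hist["val_loss"] if hist["val_loss"] is not None else hist["train_loss"][-1]
        val_losses.append(float(val))
        checkpoints.append(model.clone())

        unlab_rows = np.array([i for i, v in enumerate(ids) if int(v) not in labelled])
        if unlab_rows.size == 0:
            stop_reason = "all voxels labelled"
            break
        if it == config.max_iterations:
            break
        rnd = pseudo_label_round(model, X[unlab_rows], ids[unlab_rows],
                                 sa[unlab_rows], config, iteration=it)
        rounds.append(rnd)
        new_ids = np.array(rnd.added_0 + rnd.added_1, dtype=int)
        new_y = np.array([0] * len(rnd.added_0) + [1] * len(rnd.added_1))
        if new_ids.size:
            pool_ids = np.concatenate([pool_ids, new_ids])
            pool_labels = np.concatenate([pool_labels, new_y])
            labelled.update(int(i) for i in new_ids)
            a, b, c_, d = _split_new(new_ids, new_y, config.split, rng)
            tr_ids = np.concatenate([tr_ids, a])
            tr_y = np.concatenate([tr_y, b])
            va_ids = np.concatenate([va_ids, c_])
            va_y = np.concatenate([va_y, d])
        if rnd.stopped:
            stop_reason = rnd.reason
            break

    best = int(np.argmin(val_losses))
    result = SadResult(model=checkpoints[best], init_pool=init_pool, rounds=rounds,
                       pool_ids=pool_ids, pool_labels=pool_labels,
                       val_losses=val_losses, best_iteration=best + 1,
                       n_iterations=n_iter, alpha=alpha, sa=sa)
    result.stop_reason = stop_reason
    return result


def predict(model: BiLstmNet, data: TimeSeriesMatrix | np.ndarray,
            sa: np.ndarray | None = None, threshold: float = 0.5,
            h_max: int = ac.DEFAULT_H_MAX):
    """Per-voxel (P_NN, P_pred, class) at the given decision threshold.

    Class 1 iff ``P_pred > threshold`` (strict). SA is computed from the
    data when not supplied.
    """
    if isinstance(data, np.ndarray):
        data = TimeSeriesMatrix(values=data, dt=1.0)
    if data.units != "standardized":
        data = standardize(data)
    if sa is None:
        sa = ac.sample_autocorr(data.values, h_max).SA
    p_nn = model.predict_proba(data.values)
    p_pred = regularized_score(p_nn, np.asarray(sa, dtype=float))
    cls = (p_pred > threshold).astype(int)
    return p_nn, p_pred, cls


class SadClassifier(BaseEstimator):
    """Semi-supervised Bi-LSTM detector of activated voxel time-series.

    A scikit-learn style estimator: ``fit(X)`` needs no labels — the
    initialization pool is self-labelled from the summed sample
    autocorrelation of each row, and the network is trained iteratively on
    confident pseudo-labels. ``predict(X)`` classifies new series (rows are
    standardized internally) by thresholding the SA-regularized score.

    Parameters mirror :class:`TrainConfig`; see the module docstring for the
    procedure. ``random_state`` seeds every source of randomness (network
    initialization, train/validation splits, batch order).

    Attributes
    ----------
    model_ : BiLstmNet
        Lowest-validation-loss checkpoint.
    alpha_ : float
        Tail fraction used for initialization.
    sa_ : ndarray
        Summed sample autocorrelation of the training rows.
    pool_ids_, pool_labels_ : ndarray
        Final training pool and its (pseudo-)labels.
    val_losses_ : list of float
        Validation loss per iteration.
    n_iter_ : int
        Number of training iterations executed.
    """

    def __init__(self, c: float = 0.98, per_class_add: int = 500,
                 max_iterations: int = 20, split: float = 0.70, epochs: int = 50,
                 batch_size: int = 32, lr: float = 1e-3, threshold: float = 0.5,
                 h_max: int = ac.DEFAULT_H_MAX, alpha: float | None = None,
                 grid_step: float = 0.002, warm_start: bool = True,
                 allow_unsafe_confidence: bool = False, random_state: int = 0):
        self.c = c
        self.per_class_add = per_class_add
        self.max_iterations = max_iterations
        self.split = split
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.threshold = threshold
        self.h_max = h_max
        self.alpha = alpha
        self.grid_step = grid_step
        self.warm_start = warm_start
        self.allow_unsafe_confidence = allow_unsafe_confidence
        self.random_state = random_state

    def _config(self) -> TrainConfig:
        return TrainConfig(c=self.c, per_class_add=self.per_class_add,
                           max_iterations=self.max_iterations, split=self.split,
                           epochs=self.epochs, batch_size=self.batch_size,
                           lr=self.lr, seed=self.random_state,
                           final_threshold=self.threshold, h_max=self.h_max,
                           alpha=self.alpha, grid_step=self.grid_step,
                           warm_start=self.warm_start,
                           allow_unsafe_confidence=self.allow_unsafe_confidence)

    def fit(self, X, y=None):
        """Run the semi-supervised loop on rows of X (V, T). y is ignored."""
        result = run_sad(np.asarray(X, dtype=float), self._config())
        self.result_ = result
        self.model_ = result.model
        self.alpha_ = result.alpha
        self.sa_ = result.sa
        self.pool_ids_ = result.pool_ids
        self.pool_labels_ = result.pool_labels
        self.val_losses_ = result.val_losses
        self.n_iter_ = result.n_iterations
        self.classes_ = np.array([0, 1])
        return self

    def _check_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("SadClassifier is not fitted yet; call fit first")

    def decision_function(self, X) -> np.ndarray:
        """SA-regularized activation score P_pred per row of X."""
        self._check_fitted()
        _, p_pred, _ = predict(self.model_, np.asarray(X, dtype=float),
                               threshold=self.threshold, h_max=self.h_max)
        return p_pred

    def predict_proba(self, X) -> np.ndarray:
        p = self.decision_function(X)
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.decision_function(X) > self.threshold).astype(int)

    def score_components(self, X):
        """Both scores: raw network output P_NN and regularized P_pred."""
        self._check_fitted()
        p_nn, p_pred, cls = predict(self.model_, np.asarray(X, dtype=float),
                                    threshold=self.threshold, h_max=self.h_max)
        return p_nn, p_pred, cls
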