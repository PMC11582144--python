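"""The compact Bi-LSTM sequence classifier.

Architecture (defaults): three bidirectional LSTM blocks with per-direction
hidden sizes 15, 10 and 3. Blocks 1 and 2 emit, at every time step, the
elementwise mean of the forward and reverse hidden states, each followed by
batch normalization over the (batch, time) axes. Block 3 emits the mean of
its last forward state and the reverse state at time 0 (the reverse
recurrence's final state). A 3-to-1 affine map with a sigmoid yields one
activation probability per series. With two bias vectors per gate set
(input-side and hidden-side) the default network has 4734 trainable
parameters.

Implemented in numpy with numba-compiled recurrent kernels; training uses
Adam on the binary cross-entropy, deterministic given a seed.
"""

from __future__ import annotations

import copy
import dataclasses
import warnings

import numpy as np

from ._kernels import lstm_forward, lstm_backward

__all__ = ["SadNetworkSpec", "BiLstmNet", "count_parameters", "fit_epochs"]


@dataclasses.dataclass(frozen=True)
class SadNetworkSpec:
    """Architecture hyperparameters of the Bi-LSTM classifier."""

    input_dim: int = 1
    hidden: tuple = (15, 10, 3)
    batchnorm_after: tuple = (1, 2)  # 1-based block indices

    def __post_init__(self):
        if self.input_dim < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("input_dim and hidden sizes must be >= 1")
        if any(b not in range(1, len(self.hidden) + 1) for b in self.batchnorm_after):
            raise ValueError("batchnorm_after indices must name existing blocks")


def count_parameters(spec: SadNetworkSpec = SadNetworkSpec()) -> int:
    """Trainable parameter count implied by the spec.

    Each bidirectional block: 2 directions x (4H(Din+H) weights + 2*4H
    biases). Each batch norm: 2H affine terms. Head: H_last + 1.
    """
    total = 0
    din = spec.input_dim
    for idx, h in enumerate(spec.hidden, start=1):
        total += 2 * (4 * h * (din + h) + 8 * h)
        if idx in spec.batchnorm_after:
            total += 2 * h
        din = h  # block output = mean of the two directions -> width h
    total += spec.hidden[-1] + 1
    return total


def _dir_forward(xseq, W, b, U):
    """One LSTM direction over (T, B, Din) input; returns h and a cache."""
    T, B, din = xseq.shape
    h4 = U.shape[1]
    A = (xseq.reshape(T * B, din) @ W + b).reshape(T, B, h4)
    h, c, gates = lstm_forward(np.ascontiguousarray(A), U)
    return h, (xseq, h, c, gates)


def _dir_backward(cache, dY, W, U):
    xseq, h, c, gates = cache
    T, B, H = dY.shape
    din = W.shape[0]
    dA = lstm_backward(np.ascontiguousarray(dY), gates, c, U)
    dA2 = dA.reshape(T * B, 4 * H)
    dW = xseq.reshape(T * B, din).T @ dA2
    hprev = np.concatenate([np.zeros((1, B, H)), h[:-1]], axis=0)
    dU = hprev.reshape(T * B, H).T @ dA2
    db = dA2.sum(axis=0)
    dx = (dA2 @ W.T).reshape(T, B, din)
    return dx, dW, dU, db


class BiLstmNet:
    """Numpy/numba implementation of the Bi-LSTM activation classifier.

    Parameters are stored as a flat dict of float64 arrays; batch-norm
    running statistics are kept separately (not trainable). ``forward``
    in train mode returns a cache consumed by ``backward``; inference uses
    running statistics.
    """

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, spec: SadNetworkSpec | None = None, seed: int = 0):
        self.spec = spec if spec is not None else SadNetworkSpec()
        self.seed = int(seed)
        self.params: dict[str, np.ndarray] = {}
        self.running: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(self.seed))

    # -- construction ------------------------------------------------------
    def _init_params(self, rng) -> None:
        din = self.spec.input_dim
        for l, h in enumerate(self.spec.hidden):
            k = 1.0 / np.sqrt(h)  # uniform fan-in scheme
            for d in ("f", "b"):
                p = f"l{l}{d}"
                self.params[p + "_W"] = rng.uniform(-k, k, size=(din, 4 * h))
                self.params[p + "_U"] = rng.uniform(-k, k, size=(h, 4 * h))
                self.params[p + "_bih"] = rng.uniform(-k, k, size=4 * h)
                self.params[p + "_bhh"] = rng.uniform(-k, k, size=4 * h)
            if (l + 1) in self.spec.batchnorm_after:
                self.params[f"bn{l + 1}_gamma"] = np.ones(h)
                self.params[f"bn{l + 1}_beta"] = np.zeros(h)
                self.running[f"bn{l + 1}_mean"] = np.zeros(h)
                self.running[f"bn{l + 1}_var"] = np.ones(h)
            din = h
        d3 = self.spec.hidden[-1]
        k = 1.0 / np.sqrt(d3)
        self.params["fc_w"] = rng.uniform(-k, k, size=d3)
        self.params["fc_b"] = rng.uniform(-k, k, size=1)

    def n_parameters(self) -> int:
        """Element count of the trainable store (cross-check for the formula)."""
        return int(sum(p.size for p in self.params.values()))

    def clone(self) -> "BiLstmNet":
        new = BiLstmNet.__new__(BiLstmNet)
        new.spec = self.spec
        new.seed = self.seed
        new.params = {k: v.copy() for k, v in self.params.items()}
        new.running = {k: v.copy() for k, v in self.running.items()}
        return new

    def state_dict(self) -> dict:
        return {"spec": dataclasses.asdict(self.spec), "seed": self.seed,
                "params": copy.deepcopy(self.params),
                "running": copy.deepcopy(self.running)}

    # -- forward -----------------------------------------------------------
    def _bi_block(self, x, l, last_only, cache):
        p = self.params
        hf, cf = _dir_forward(x, p[f"l{l}f_W"], p[f"l{l}f_bih"] + p[f"l{l}f_bhh"],
                              p[f"l{l}f_U"])
        xrev = np.ascontiguousarray(x[::-1])
        hb, cb = _dir_forward(xrev, p[f"l{l}b_W"], p[f"l{l}b_bih"] + p[f"l{l}b_bhh"],
                              p[f"l{l}b_U"])
        cache[f"l{l}"] = (cf, cb)
        if last_only:
            # last forward state and the reverse state at original t=0
            return 0.5 * (hf[-1] + hb[-1])
        return 0.5 * (hf + hb[::-1])

    def _bn(self, y, idx, train, cache):
        gamma = self.params[f"bn{idx}_gamma"]
        beta = self.params[f"bn{idx}_beta"]
        if train:
            axes = tuple(range(y.ndim - 1))
            mu = y.mean(axis=axes)
            var = y.var(axis=axes)
            n = int(np.prod([y.shape[a] for a in axes]))
            xhat = (y - mu) / np.sqrt(var + self.BN_EPS)
            m = self.BN_MOMENTUM
            self.running[f"bn{idx}_mean"] *= (1 - m)
            self.running[f"bn{idx}_mean"] += m * mu
            unbiased = var * n / max(n - 1, 1)
            self.running[f"bn{idx}_var"] *= (1 - m)
            self.running[f"bn{idx}_var"] += m * unbiased
            cache[f"bn{idx}"] = (xhat, var)
            return gamma * xhat + beta
        mu = self.running[f"bn{idx}_mean"]
        var = self.running[f"bn{idx}_var"]
        return gamma * (y - mu) / np.sqrt(var + self.BN_EPS) + beta

    def forward(self, X, train: bool = False):
        """Logits for a batch of series.

        Parameters
        ----------
        X : ndarray (B, T)
            Standardized series, one per row.

        Returns
        -------
        z : ndarray (B,) pre-sigmoid logits.
        cache : dict or None; pass to :meth:`backward` when ``train=True``.
        """
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] < 2:
            raise ValueError("X must be (B, T) with T >= 2")
        cache: dict = {}
        n_blocks = len(self.spec.hidden)
        x = np.ascontiguousarray(X.T[:, :, None])  # (T, B, 1)
        for l in range(n_blocks):
            last = l == n_blocks - 1
            x = self._bi_block(x, l, last, cache)
            if (l + 1) in self.spec.batchnorm_after:
                x = self._bn(x, l + 1, train, cache)
        cache["head_in"] = x  # (B, D3)
        z = x @ self.params["fc_w"] + self.params["fc_b"][0]
        return (z, cache) if train else (z, None)

    def predict_proba(self, X, chunk: int = 512) -> np.ndarray:
        """Activation probability per series, strictly inside (0, 1)."""
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        for start in range(0, X.shape[0], chunk):
            z, _ = self.forward(X[start:start + chunk], train=False)
            out[start:start + chunk] = 1.0 / (1.0 + np.exp(-z))
        return np.clip(out, 1e-12, 1.0 - 1e-12)

    # -- backward ----------------------------------------------------------
    def backward(self, cache, dz):
        """Gradients of the scalar loss given d(loss)/d(logits).

        Returns a dict with the same keys as :attr:`params`.
        """
        grads = {k: None for k in self.params}
        a = cache["head_in"]
        grads["fc_w"] = a.T @ dz
        grads["fc_b"] = np.array([dz.sum()])
        dx = dz[:, None] * self.params["fc_w"][None, :]  # (B, D3)
        n_blocks = len(self.spec.hidden)
        for l in range(n_blocks - 1, -1, -1):
            if (l + 1) in self.spec.batchnorm_after:
                dx = self._bn_backward(dx, l + 1, cache, grads)
            dx = self._bi_block_backward(dx, l, cache, grads,
                                         last_only=(l == n_blocks - 1))
        return grads

    def _bn_backward(self, dout, idx, cache, grads):
        xhat, var = cache[f"bn{idx}"]
        gamma = self.params[f"bn{idx}_gamma"]
        axes = tuple(range(dout.ndim - 1))
        grads[f"bn{idx}_gamma"] = (dout * xhat).sum(axis=axes)
        grads[f"bn{idx}_beta"] = dout.sum(axis=axes)
        dxhat = dout * gamma
        dx = (dxhat - dxhat.mean(axis=axes)
              - xhat * (dxhat * xhat).mean(axis=axes)) / np.sqrt(var + self.BN_EPS)
        return dx

    def _bi_block_backward(self, dout, l, cache, grads, last_only):
        cf, cb = cache[f"l{l}"]
        T, B, H = cf[1].shape
        if last_only:
            dYf = np.zeros((T, B, H))
            dYf[-1] = 0.5 * dout
            dYb = np.zeros((T, B, H))
            dYb[-1] = 0.5 * dout
        else:
            dYf = 0.5 * dout
            dYb = np.ascontiguousarray(0.5 * dout[::-1])
        p = self.params
        dxf, dWf, dUf, dbf = _dir_backward(cf, dYf, p[f"l{l}f_W"], p[f"l{l}f_U"])
        dxb, dWb, dUb, dbb = _dir_backward(cb, dYb, p[f"l{l}b_W"], p[f"l{l}b_U"])
        grads[f"l{l}f_W"], grads[f"l{l}f_U"] = dWf, dUf
        grads[f"l{l}f_bih"] = grads[f"l{l}f_bhh"] = dbf
        grads[f"l{l}b_W"], grads[f"l{l}b_U"] = dWb, dUb
        grads[f"l{l}b_bih"] = grads[f"l{l}b_bhh"] = dbb
        return dxf + dxb[::-1]


def _bce_from_logits(z, y):
    """Stable binary cross-entropy and its gradient w.r.t. the logits."""
    loss = np.mean(y * np.logaddexp(0.0, -z) + (1 - y) * np.logaddexp(0.0, z))
    p = 1.0 / (1.0 + np.exp(-z))
    return float(loss), (p - y) / z.size


def fit_epochs(net: BiLstmNet, X, y, *, X_val=None, y_val=None, epochs: int = 50,
               batch_size: int = 32, lr: float = 1e-3, seed: int = 0) -> dict:
    """Train with Adam on binary cross-entropy; deterministic given the seed.

    Returns a history dict with per-epoch mean training loss and, when a
    validation set is supplied, the final validation loss (computed in
    inference mode with running batch-norm statistics).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X and y length mismatch")
    classes = np.unique(y)
    if classes.size < 2:
        warnings.warn("training labels contain a single class; "
                      "cross-entropy is still defined but the fit is degenerate",
                      stacklevel=2)
    rng = np.random.default_rng(seed)
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    v = {k: np.zeros_like(p) for k, p in net.params.items()}
    b1, b2, eps = 0.9, 0.999, 1e-8
    step = 0
    history = {"train_loss": [], "val_loss": None}
    n = X.shape[0]
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            z, cache = net.forward(X[idx], train=True)
            loss, dz = _bce_from_logits(z, y[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite training loss")
            losses.append(loss)
            grads = net.backward(cache, dz)
            step += 1
            corr = np.sqrt(1 - b2 ** step) / (1 - b1 ** step)
            for k, g in grads.items():
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                net.params[k] -= lr * corr * m[k] / (np.sqrt(v[k]) + eps)
        history["train_loss"].append(float(np.mean(losses)))
    if X_val is not None and len(X_val):
        zv, _ = net.forward(np.asarray(X_val, dtype=float), train=False)
        val_loss, _ = _bce_from_logits(zv, np.asarray(y_val, dtype=float).ravel())
        history["val_loss"] = val_loss
    return history
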