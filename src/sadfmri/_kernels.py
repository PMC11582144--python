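"""Numba-compiled recurrent kernels for the Bi-LSTM network.

Only the sequential part of the LSTM lives here: the per-time-step gate
updates (forward) and the backpropagation-through-time recursion (backward).
The hidden sizes are tiny (<= 15), so the recurrent products are written as
fused explicit loops — at these shapes that beats per-step BLAS dispatch by
an order of magnitude. All large, recurrence-free matrix products (input
projections, weight-gradient contractions) are batched outside in numpy.

Gate layout along the last axis is [i, f, g, o] (input, forget, cell, output),
each of width H.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def lstm_forward(A, U):
    """Run an LSTM over a sequence of pre-computed input projections.

    Parameters
    ----------
    A : float64 (T, B, 4H)
        ``x_t @ W + b_ih + b_hh`` for every step.
    U : float64 (H, 4H)
        Recurrent weights.

    Returns
    -------
    h, c : (T, B, H) hidden and cell states.
    gates : (T, B, 4H) post-activation gate values (cached for backward).
    """
    T, B, H4 = A.shape
    H = H4 // 4
    h = np.zeros((T, B, H))
    c = np.zeros((T, B, H))
    gates = np.empty((T, B, H4))
    a = np.empty(H4)
    for t in range(T):
        for b in range(B):
            for j in range(H4):
                a[j] = A[t, b, j]
            if t > 0:
                for k in range(H):
                    hv = h[t - 1, b, k]
                    for j in range(H4):
                        a[j] += hv * U[k, j]
            for k in range(H):
                ig = 1.0 / (1.0 + np.exp(-a[k]))
                fg = 1.0 / (1.0 + np.exp(-a[H + k]))
                gg = np.tanh(a[2 * H + k])
                og = 1.0 / (1.0 + np.exp(-a[3 * H + k]))
                cprev = c[t - 1, b, k] if t > 0 else 0.0
                cc = fg * cprev + ig * gg
                c[t, b, k] = cc
                h[t, b, k] = og * np.tanh(cc)
                gates[t, b, k] = ig
                gates[t, b, H + k] = fg
                gates[t, b, 2 * H + k] = gg
                gates[t, b, 3 * H + k] = og
    return h, c, gates


@njit(cache=True, fastmath=True)
def lstm_backward(dY, gates, c, U):
    """Backpropagation through time for :func:`lstm_forward`.

    Parameters
    ----------
    dY : float64 (T, B, H)
        Gradient of the loss w.r.t. the hidden state emitted at every step
        (zero rows where a step's output is unused).

    Returns
    -------
    dA : (T, B, 4H) gradient w.r.t. the pre-activation input projections;
        weight/bias/input gradients follow from it by plain matrix products.
    """
    T, B, H = dY.shape
    H4 = 4 * H
    dA = np.empty((T, B, H4))
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for t in range(T - 1, -1, -1):
        for b in range(B):
            for k in range(H):
                dht = dY[t, b, k] + dh[b, k]
                ig = gates[t, b, k]
                fg = gates[t, b, H + k]
                gg = gates[t, b, 2 * H + k]
                og = gates[t, b, 3 * H + k]
                tc = np.tanh(c[t, b, k])
                do = dht * tc
                dct = dc[b, k] + dht * og * (1.0 - tc * tc)
                cprev = c[t - 1, b, k] if t > 0 else 0.0
                dA[t, b, k] = dct * gg * ig * (1.0 - ig)
                dA[t, b, H + k] = dct * cprev * fg * (1.0 - fg)
                dA[t, b, 2 * H + k] = dct * ig * (1.0 - gg * gg)
                dA[t, b, 3 * H + k] = do * og * (1.0 - og)
                dc[b, k] = dct * fg
            # dh_{t-1} = dA_t @ U^T (row k of U is contiguous)
            for k in range(H):
                acc = 0.0
                for j in range(H4):
                    acc += dA[t, b, j] * U[k, j]
                dh[b, k] = acc
    return dA
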