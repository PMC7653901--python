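"""Stacked gated-recurrent-unit sequence regressor in pure numpy.

Gate equations per layer (reset r, update z, candidate n):

    r_t = sigmoid(W_ir x_t + b_ir + W_hr h_{t-1} + b_hr)
    z_t = sigmoid(W_iz x_t + b_iz + W_hz h_{t-1} + b_hz)
    n_t = tanh(W_in x_t + b_in + r_t * (W_hn h_{t-1} + b_hn))
    h_t = (1 - z_t) * n_t + z_t * h_{t-1}

The hidden-state sequence of the last (size-1) layer is the regression
output directly — no extra projection.  Gradients are computed by
backpropagation through time; correctness is pinned to a finite-difference
oracle in the test suite.  Parameters are float64 throughout, so training is
bit-for-bit reproducible for a fixed seed and batch order.
"""

from __future__ import annotations

from typing import Dict, Sequence, Tuple

import numpy as np

__all__ = ["GRUStack", "Adam", "mse_loss"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class GRUStack:
    """A stack of unidirectional GRU layers, e.g. sizes 9 -> 18 -> 9 -> 1.

    Parameters live in ``self.params`` as a flat dict:
    ``W_ih_l{i}`` (3H, in), ``W_hh_l{i}`` (3H, H), ``b_ih_l{i}``, ``b_hh_l{i}``
    with gate blocks stacked in (r, z, n) order.
    """

    def __init__(self, layer_sizes: Sequence[int], rng: np.random.Generator):
        if len(layer_sizes) < 2:
            raise ValueError("need at least input and one hidden size")
        self.layer_sizes = tuple(int(s) for s in layer_sizes)
        self.n_layers = len(self.layer_sizes) - 1
        self.params: Dict[str, np.ndarray] = {}
        for i in range(self.n_layers):
            n_in, n_h = self.layer_sizes[i], self.layer_sizes[i + 1]
            bound = 1.0 / np.sqrt(n_h)
            self.params[f"W_ih_l{i}"] = rng.uniform(-bound, bound, (3 * n_h, n_in))
            self.params[f"W_hh_l{i}"] = rng.uniform(-bound, bound, (3 * n_h, n_h))
            self.params[f"b_ih_l{i}"] = rng.uniform(-bound, bound, 3 * n_h)
            self.params[f"b_hh_l{i}"] = rng.uniform(-bound, bound, 3 * n_h)

    # -- forward ----------------------------------------------------------

    def _layer_forward(self, i: int, x: np.ndarray, cache: bool):
        """x: (T, B, n_in) -> h_seq: (T, B, n_h); caches per-step internals."""
        T, B, _ = x.shape
        n_h = self.layer_sizes[i + 1]
        W_ih = self.params[f"W_ih_l{i}"]
        W_hh = self.params[f"W_hh_l{i}"]
        b_ih = self.params[f"b_ih_l{i}"]
        b_hh = self.params[f"b_hh_l{i}"]
        # input projections for all steps at once
        gi = x.reshape(T * B, -1) @ W_ih.T + b_ih
        gi = gi.reshape(T, B, 3 * n_h)
        h = np.zeros((B, n_h))
        h_seq = np.empty((T, B, n_h))
        caches = [] if cache else None
        W_hh_T = W_hh.T
        for t in range(T):
            gh = h @ W_hh_T + b_hh
            gir, giz, gin = gi[t, :, :n_h], gi[t, :, n_h:2 * n_h], gi[t, :, 2 * n_h:]
            ghr, ghz, ghn = gh[:, :n_h], gh[:, n_h:2 * n_h], gh[:, 2 * n_h:]
            r = _sigmoid(gir + ghr)
            z = _sigmoid(giz + ghz)
            n = np.tanh(gin + r * ghn)
            h_new = (1.0 - z) * n + z * h
            if cache:
                caches.append((h, r, z, n, ghn))
            h = h_new
            h_seq[t] = h
        return h_seq, caches

    def forward(self, x: np.ndarray, cache: bool = False):
        """Run the full stack.  Returns (output (T,B,H_last), state)."""
        state = []
        inp = x
        for i in range(self.n_layers):
            h_seq, caches = self._layer_forward(i, inp, cache)
            if cache:
                state.append((inp, h_seq, caches))
            inp = h_seq
        return inp, state

    # -- backward ---------------------------------------------------------

    def _layer_backward(self, i: int, x, h_seq, caches, dh_seq):
        T, B, n_in = x.shape
        n_h = self.layer_sizes[i + 1]
        W_ih = self.params[f"W_ih_l{i}"]
        W_hh = self.params[f"W_hh_l{i}"]
        A_in = np.empty((T, B, 3 * n_h))  # grads wrt input-side preactivations
        A_h = np.empty((T, B, 3 * n_h))   # grads wrt hidden-side preactivations
        dh_next = np.zeros((B, n_h))
        W_hh_mat = W_hh  # (3H, H)
        for t in range(T - 1, -1, -1):
            h_prev, r, z, n, ghn = caches[t]
            dh = dh_seq[t] + dh_next
            dn = dh * (1.0 - z)
            dz = dh * (h_prev - n)
            dh_prev = dh * z
            dan = dn * (1.0 - n * n)
            dr = dan * ghn
            dghn = dan * r
            dar = dr * r * (1.0 - r)
            daz = dz * z * (1.0 - z)
            A_in[t, :, :n_h] = dar
            A_in[t, :, n_h:2 * n_h] = daz
            A_in[t, :, 2 * n_h:] = dan
            A_h[t, :, :n_h] = dar
            A_h[t, :, n_h:2 * n_h] = daz
            A_h[t, :, 2 * n_h:] = dghn
            dh_next = dh_prev + A_h[t].reshape(B, 3 * n_h) @ W_hh_mat
        flat_A_in = A_in.reshape(T * B, 3 * n_h)
        flat_A_h = A_h.reshape(T * B, 3 * n_h)
        # h_prev sequence: zeros at t=0 then h_seq[:-1]
        h_prev_seq = np.concatenate(
            [np.zeros((1, B, n_h)), h_seq[:-1]], axis=0
        ).reshape(T * B, n_h)
        grads = {
            f"W_ih_l{i}": flat_A_in.T @ x.reshape(T * B, n_in),
            f"W_hh_l{i}": flat_A_h.T @ h_prev_seq,
            f"b_ih_l{i}": flat_A_in.sum(axis=0),
            f"b_hh_l{i}": flat_A_h.sum(axis=0),
        }
        dx = (flat_A_in @ W_ih).reshape(T, B, n_in)
        return grads, dx

    def backward(self, state, dy: np.ndarray) -> Dict[str, np.ndarray]:
        """Gradient of a scalar loss wrt all parameters, given dL/d(output)."""
        grads: Dict[str, np.ndarray] = {}
        dh_seq = dy
        for i in range(self.n_layers - 1, -1, -1):
            x, h_seq, caches = state[i]
            layer_grads, dh_seq = self._layer_backward(i, x, h_seq, caches, dh_seq)
            grads.update(layer_grads)
        return grads


def mse_loss(pred: np.ndarray, target: np.ndarray) -> Tuple[float, np.ndarray]:
    """Mean squared error and its gradient wrt ``pred``."""
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = 2.0 * diff / diff.size
    return loss, grad


class Adam:
    """Adam optimizer over a dict of parameter arrays."""

    def __init__(self, params: Dict[str, np.ndarray], lr: float = 1e-3,
                 betas: Tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: Dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * (g * g)
            m_hat = self.m[k] / b1t
            v_hat = self.v[k] / b2t
            p -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
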