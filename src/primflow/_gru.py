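"""Minimal recurrent core: GRU layers with exact backpropagation through
time, plus an Adam optimizer and gradient clipping.

Gate convention (per step, input x_t, state h_{t-1}):

    r = sigmoid(x W_xr + b_xr + h W_hr + b_hr)
    z = sigmoid(x W_xz + b_xz + h W_hz + b_hz)
    n = tanh(x W_xn + b_xn + r * (h W_hn + b_hn))
    h_t = (1 - z) * n + z * h_{t-1}

Weights are packed as ``Wx`` (D, 3H), ``Wh`` (H, 3H) with gate order
[r | z | n] and biases ``bx``, ``bh`` (3H,).

Layout for speed on one CPU: the input projection of a whole sequence and
all weight-gradient contractions are single BLAS matrix products; only the
strictly sequential hidden-to-hidden recursion runs in a per-step loop,
which is JIT-compiled with numba when available (a pure-NumPy loop is the
fallback).  All gradients are exact; a finite-difference check lives in
the test suite.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

# The recurrent workload is dominated by many small matrix products; a
# spinning BLAS thread pool slows those by an order of magnitude on
# single-core machines, so BLAS is pinned to one thread for the process.
try:  # pragma: no cover
    from threadpoolctl import threadpool_limits

    _BLAS_LIMIT = threadpool_limits(limits=1, user_api="blas")
except Exception:  # pragma: no cover
    _BLAS_LIMIT = None


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    np.negative(np.abs(x), out=out)
    np.exp(out, out=out)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + out[pos])
    neg = ~pos
    out[neg] = out[neg] / (1.0 + out[neg])
    return out


def init_gru_params(
    rng: np.random.Generator, in_dim: int, hidden: int, dtype=np.float32
) -> dict[str, np.ndarray]:
    """Uniform(-k, k) initialization with k = 1/sqrt(hidden)."""
    k = 1.0 / np.sqrt(hidden)
    u = lambda *shape: rng.uniform(-k, k, size=shape).astype(dtype)  # noqa: E731
    return {
        "Wx": u(in_dim, 3 * hidden),
        "Wh": u(hidden, 3 * hidden),
        "bx": u(3 * hidden),
        "bh": u(3 * hidden),
    }


# ---------------------------------------------------------------------------
# Sequential loops (numba-compiled when available)
# ---------------------------------------------------------------------------


def _fwd_loop_py(XP, Wh, bh, h0, Hs, R, Z, N, HN):
    T, B, H3 = XP.shape
    H = H3 // 3
    h = h0
    Hs[0] = h0
    for t in range(T):
        hp = h @ Wh + bh
        r = sigmoid(XP[t, :, :H] + hp[:, :H])
        z = sigmoid(XP[t, :, H : 2 * H] + hp[:, H : 2 * H])
        hn = hp[:, 2 * H :]
        n = np.tanh(XP[t, :, 2 * H :] + r * hn)
        h = (1.0 - z) * n + z * h
        R[t], Z[t], N[t], HN[t] = r, z, n, hn
        Hs[t + 1] = h


def _bwd_loop_py(WhT, Hs, R, Z, N, HN, dY, dh_last, dXP, dHP):
    T, B, H = R.shape
    dh = dh_last.copy()
    for t in range(T - 1, -1, -1):
        dh = dh + dY[t]
        r, z, n, hn = R[t], Z[t], N[t], HN[t]
        h_prev = Hs[t]
        dz = dh * (h_prev - n) * z * (1.0 - z)
        dn_pre = dh * (1.0 - z) * (1.0 - n * n)
        dr_pre = dn_pre * hn * r * (1.0 - r)
        dXP[t, :, :H] = dr_pre
        dXP[t, :, H : 2 * H] = dz
        dXP[t, :, 2 * H :] = dn_pre
        dHP[t, :, :H] = dr_pre
        dHP[t, :, H : 2 * H] = dz
        dHP[t, :, 2 * H :] = dn_pre * r
        dh = dh * z + dHP[t] @ WhT
    return dh


if _HAVE_NUMBA:

    @numba.njit(cache=True, fastmath=True)
    def _fwd_loop_nb(XP, Wh, bh, h0, Hs, R, Z, N, HN):  # pragma: no cover
        T, B, H3 = XP.shape
        H = H3 // 3
        h = h0.copy()
        for b in range(B):
            for j in range(H):
                Hs[0, b, j] = h0[b, j]
        for t in range(T):
            hp = np.dot(h, Wh)
            for b in range(B):
                for j in range(H):
                    rv = 1.0 / (
                        1.0 + np.exp(-(XP[t, b, j] + hp[b, j] + bh[j]))
                    )
                    zv = 1.0 / (
                        1.0
                        + np.exp(
                            -(XP[t, b, H + j] + hp[b, H + j] + bh[H + j])
                        )
                    )
                    hn = hp[b, 2 * H + j] + bh[2 * H + j]
                    nv = np.tanh(XP[t, b, 2 * H + j] + rv * hn)
                    hv = (1.0 - zv) * nv + zv * h[b, j]
                    R[t, b, j] = rv
                    Z[t, b, j] = zv
                    N[t, b, j] = nv
                    HN[t, b, j] = hn
                    h[b, j] = hv
                    Hs[t + 1, b, j] = hv

    @numba.njit(cache=True, fastmath=True)
    def _bwd_loop_nb(
        WhT, Hs, R, Z, N, HN, dY, dh_last, dXP, dHP
    ):  # pragma: no cover
        T, B, H = R.shape
        dh = dh_last.copy()
        for t in range(T - 1, -1, -1):
            for b in range(B):
                for j in range(H):
                    d = dh[b, j] + dY[t, b, j]
                    r = R[t, b, j]
                    z = Z[t, b, j]
                    n = N[t, b, j]
                    hn = HN[t, b, j]
                    dz = d * (Hs[t, b, j] - n) * z * (1.0 - z)
                    dnp = d * (1.0 - z) * (1.0 - n * n)
                    drp = dnp * hn * r * (1.0 - r)
                    dXP[t, b, j] = drp
                    dXP[t, b, H + j] = dz
                    dXP[t, b, 2 * H + j] = dnp
                    dHP[t, b, j] = drp
                    dHP[t, b, H + j] = dz
                    dHP[t, b, 2 * H + j] = dnp * r
                    dh[b, j] = d * z
            dcarry = np.dot(dHP[t], WhT)
            for b in range(B):
                for j in range(H):
                    dh[b, j] += dcarry[b, j]
        return dh

    _fwd_loop = _fwd_loop_nb
    _bwd_loop = _bwd_loop_nb
else:  # pragma: no cover
    _fwd_loop = _fwd_loop_py

    def _bwd_loop(WhT, Hs, R, Z, N, HN, dY, dh_last, dXP, dHP):
        return _bwd_loop_py(WhT, Hs, R, Z, N, HN, dY, dh_last, dXP, dHP)


# ---------------------------------------------------------------------------
# Public forward / backward
# ---------------------------------------------------------------------------


def gru_forward(
    X: np.ndarray, h0: np.ndarray, P: dict[str, np.ndarray]
) -> tuple[np.ndarray, dict]:
    """Run a GRU over X (T, B, D) from state h0 (B, H).

    Returns the state sequence Hs (T+1, B, H) with Hs[0] = h0, plus the
    cache needed for the backward pass.
    """
    T, B, D = X.shape
    H = h0.shape[1]
    dt = h0.dtype
    XP = (X.reshape(T * B, D) @ P["Wx"] + P["bx"]).reshape(T, B, 3 * H)
    Hs = np.empty((T + 1, B, H), dtype=dt)
    R = np.empty((T, B, H), dtype=dt)
    Z = np.empty_like(R)
    N = np.empty_like(R)
    HN = np.empty_like(R)
    _fwd_loop(
        XP,
        np.ascontiguousarray(P["Wh"]),
        np.ascontiguousarray(P["bh"]),
        np.ascontiguousarray(h0),
        Hs,
        R,
        Z,
        N,
        HN,
    )
    cache = {"X": X, "Hs": Hs, "R": R, "Z": Z, "N": N, "HN": HN}
    return Hs, cache


def gru_backward(
    P: dict[str, np.ndarray],
    cache: dict,
    dY: np.ndarray | None,
    dh_last: np.ndarray | None,
) -> tuple[np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Backpropagate through a GRU run.

    ``dY`` (T, B, H) is the gradient with respect to every output state
    (may be None), ``dh_last`` (B, H) an extra gradient on the final
    state.  Returns (dX, dh0, grads).
    """
    X, Hs = cache["X"], cache["Hs"]
    R, Z, N, HN = cache["R"], cache["Z"], cache["N"], cache["HN"]
    T, B, D = X.shape
    H = Hs.shape[2]
    dt = Hs.dtype
    if dY is None:
        dY = np.zeros((T, B, H), dtype=dt)
    if dh_last is None:
        dh_last = np.zeros((B, H), dtype=dt)
    dXP = np.empty((T, B, 3 * H), dtype=dt)
    dHP = np.empty((T, B, 3 * H), dtype=dt)
    WhT = np.ascontiguousarray(P["Wh"].T)
    dh0 = _bwd_loop(
        WhT,
        Hs,
        R,
        Z,
        N,
        HN,
        np.ascontiguousarray(dY),
        np.ascontiguousarray(dh_last),
        dXP,
        dHP,
    )
    flat_dXP = dXP.reshape(T * B, 3 * H)
    flat_dHP = dHP.reshape(T * B, 3 * H)
    grads = {
        "Wx": X.reshape(T * B, D).T @ flat_dXP,
        "Wh": Hs[:-1].reshape(T * B, H).T @ flat_dHP,
        "bx": flat_dXP.sum(axis=0),
        "bh": flat_dHP.sum(axis=0),
    }
    dX = (flat_dXP @ P["Wx"].T).reshape(T, B, D)
    return dX, dh0, grads


def gru_cell_step(
    x: np.ndarray, h: np.ndarray, P: dict[str, np.ndarray]
) -> np.ndarray:
    """Single forward GRU step (used for autoregressive decoding)."""
    H = h.shape[1]
    xp = x @ P["Wx"] + P["bx"]
    hp = h @ P["Wh"] + P["bh"]
    r = sigmoid(xp[:, :H] + hp[:, :H])
    z = sigmoid(xp[:, H : 2 * H] + hp[:, H : 2 * H])
    n = np.tanh(xp[:, 2 * H :] + r * hp[:, 2 * H :])
    return (1.0 - z) * n + z * h


def clip_global_norm(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Scale all gradients in place so their global L2 norm <= max_norm."""
    total = 0.0
    for g in grads.values():
        total += float(np.sum(g.astype(np.float64) ** 2))
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for g in grads.values():
            g *= scale
    return norm


class Adam:
    """Adaptive-moment gradient optimizer over a flat dict of arrays.

    ``weight_decay`` is decoupled (applied directly to the weights, not
    through the moments) and only touches matrices, never bias vectors.
    """

    def __init__(
        self,
        params: dict[str, np.ndarray],
        lr: float = 5e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for k, p in self.params.items():
            g = grads[k]
            m = self.m[k]
            v = self.v[k]
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * (g * g)
            if self.weight_decay and p.ndim == 2:
                p -= self.lr * self.weight_decay * p
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
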