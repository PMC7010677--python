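"""Gated-recurrent-unit primitives and the stacked bidirectional engine.

The recurrent cell implemented here uses a logistic reset gate ``r`` and
update gate ``z`` and a ReLU candidate state::

    r      = sigmoid(U_r x + W_r h_prev + b_r)
    z      = sigmoid(U_z x + W_z h_prev + b_z)
    h_cand = act(U x + W (r * h_prev) + b_h)        act = ReLU (or tanh)
    h      = (1 - z) * h_prev + z * h_cand

The network stacks L such cells per direction.  The forward-time path and
the backward-time path are completely separate recursions with separate
weights and separate affine output heads; their outputs are never merged.
Layer k > 0 of a path consumes the hidden sequence of layer k - 1 of the
*same* path only.

All batched tensors inside the engine are time-major ``(T, B, ...)``.  The
per-timestep recurrences are compiled with numba when it is available and
fall back to identical pure-numpy loops otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

try:  # pragma: no cover - exercised implicitly
    import numba

    def _jit(fn):
        return numba.njit(cache=True, fastmath=True)(fn)

except Exception:  # pragma: no cover

    def _jit(fn):
        return fn


__all__ = ["GRUCellParams", "NetworkParams", "gru_cell_step"]


@dataclass
class GRUCellParams:
    """Weights of one GRU cell.

    ``U_r, U_z, U`` are input-to-hidden matrices of shape ``(H, D)``;
    ``W_r, W_z, W`` are hidden-to-hidden matrices of shape ``(H, H)``;
    ``b_r, b_z, b_h`` are per-gate bias vectors (zeros when omitted).
    """

    U_r: np.ndarray
    U_z: np.ndarray
    U: np.ndarray
    W_r: np.ndarray
    W_z: np.ndarray
    W: np.ndarray
    b_r: np.ndarray = None
    b_z: np.ndarray = None
    b_h: np.ndarray = None

    def __post_init__(self) -> None:
        H, D = np.shape(self.U_r)
        for name in ("U_r", "U_z", "U"):
            if np.shape(getattr(self, name)) != (H, D):
                raise ValueError(f"{name} must have shape {(H, D)}")
        for name in ("W_r", "W_z", "W"):
            if np.shape(getattr(self, name)) != (H, H):
                raise ValueError(f"{name} must have shape {(H, H)}")
        dtype = np.asarray(self.U_r).dtype
        for name in ("b_r", "b_z", "b_h"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(H, dtype=dtype))
            elif np.shape(getattr(self, name)) != (H,):
                raise ValueError(f"{name} must have shape {(H,)}")
        for name in ("U_r", "U_z", "U", "W_r", "W_z", "W", "b_r", "b_z", "b_h"):
            arr = np.asarray(getattr(self, name))
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, arr)

    @property
    def hidden_size(self) -> int:
        return self.U_r.shape[0]

    @property
    def input_size(self) -> int:
        return self.U_r.shape[1]

    def arrays(self) -> list[np.ndarray]:
        return [self.U_r, self.U_z, self.U, self.W_r, self.W_z, self.W,
                self.b_r, self.b_z, self.b_h]


@dataclass
class NetworkParams:
    """All weights of the stacked bidirectional network.

    ``layers[k]`` holds the (forward-path, backward-path) cell pair of
    layer k; layer 0 consumes the scalar measurement sample per timestep.
    ``V_f, c_f`` and ``V_b, c_b`` are the affine hidden-to-output heads of
    the two paths (linear, since the network regresses a continuous
    voluntary-motion signal under an MSE loss).
    """

    layers: list[tuple[GRUCellParams, GRUCellParams]]
    V_f: np.ndarray
    c_f: np.ndarray
    V_b: np.ndarray
    c_b: np.ndarray
    activation: str = "relu"

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("need at least one layer")
        if self.layers[0][0].input_size != 1:
            raise ValueError("layer 0 must take the scalar sample (input size 1)")
        for k in range(1, len(self.layers)):
            for d in (0, 1):
                if self.layers[k][d].input_size != self.layers[k - 1][d].hidden_size:
                    raise ValueError(
                        f"layer {k} input size must equal layer {k - 1} hidden size"
                    )
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be 'relu' or 'tanh'")
        H = self.layers[-1][0].hidden_size
        self.V_f = np.asarray(self.V_f).reshape(H)
        self.V_b = np.asarray(self.V_b).reshape(H)
        self.c_f = np.asarray(self.c_f).reshape(1)
        self.c_b = np.asarray(self.c_b).reshape(1)

    @property
    def n_layers(self) -> int:
        return len(self.layers)

    @property
    def hidden_size(self) -> int:
        return self.layers[-1][0].hidden_size

    @property
    def dtype(self):
        return self.layers[0][0].U_r.dtype

    def arrays(self) -> list[np.ndarray]:
        """Canonical flat list of all weight arrays (optimizer order)."""
        out: list[np.ndarray] = []
        for fwd, bwd in self.layers:
            out.extend(fwd.arrays())
            out.extend(bwd.arrays())
        out.extend([self.V_f, self.c_f, self.V_b, self.c_b])
        return out

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            layers=[
                (
                    GRUCellParams(*[a.copy() for a in fwd.arrays()]),
                    GRUCellParams(*[a.copy() for a in bwd.arrays()]),
                )
                for fwd, bwd in self.layers
            ],
            V_f=self.V_f.copy(),
            c_f=self.c_f.copy(),
            V_b=self.V_b.copy(),
            c_b=self.c_b.copy(),
            activation=self.activation,
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def gru_cell_step(
    x_t: np.ndarray, h_prev: np.ndarray, p: GRUCellParams, activation: str = "relu"
) -> np.ndarray:
    """Advance one GRU cell by one timestep (reference semantics).

    Gates are elementwise in (0, 1); the ReLU candidate is elementwise
    nonnegative.  The engine's batched loops compute exactly this map.
    """
    x_t = np.asarray(x_t, dtype=p.U_r.dtype).reshape(p.input_size)
    h_prev = np.asarray(h_prev, dtype=p.U_r.dtype).reshape(p.hidden_size)
    r = _sigmoid(p.U_r @ x_t + p.W_r @ h_prev + p.b_r)
    z = _sigmoid(p.U_z @ x_t + p.W_z @ h_prev + p.b_z)
    pre = p.U @ x_t + p.W @ (r * h_prev) + p.b_h
    h_cand = np.maximum(pre, 0.0) if activation == "relu" else np.tanh(pre)
    return (1.0 - z) * h_prev + z * h_cand


# ---------------------------------------------------------------------------
# batched time-major engine
# ---------------------------------------------------------------------------


def _fwd_loop_impl(Xp, WrzT, WT, H_seq, r_out, z_out, hc_out, relu, one):
    # `one` is a scalar of the working dtype: float literals would promote
    # float32 arrays to float64 under numba.  Array expressions (not scalar
    # loops) let LLVM vectorize the transcendentals under fastmath.
    T, B, H3 = Xp.shape
    H = H3 // 3
    zero = one - one
    gates = np.empty((B, 2 * H), dtype=Xp.dtype)
    cand = np.empty((B, H), dtype=Xp.dtype)
    for t in range(T):
        h = H_seq[t]
        np.dot(h, WrzT, gates)
        rz = one / (one + np.exp(-(Xp[t, :, : 2 * H] + gates)))
        rt = rz[:, :H]
        zt = rz[:, H:]
        rh = rt * h
        np.dot(rh, WT, cand)
        ah = Xp[t, :, 2 * H :] + cand
        if relu:
            ht = ah * (ah > zero)
        else:
            ht = np.tanh(ah)
        r_out[t] = rt
        z_out[t] = zt
        hc_out[t] = ht
        H_seq[t + 1] = (one - zt) * h + zt * ht


def _bwd_loop_impl(H_seq, r, z, hc, dH, Wr, Wz, W, dar_all, daz_all, dah_all, relu, one):
    # The weight gradients sum over time, so they are computed outside this
    # loop as single large gemms from the stored gate gradients; only the
    # hidden-state recursion stays per-timestep.
    T, B, H = dH.shape
    zero = one - one
    dh = np.zeros((B, H), dtype=dH.dtype)
    drh = np.empty((B, H), dtype=dH.dtype)
    tmp1 = np.empty((B, H), dtype=dH.dtype)
    tmp2 = np.empty((B, H), dtype=dH.dtype)
    for t in range(T - 1, -1, -1):
        dh = dh + dH[t]
        h = H_seq[t]
        rt = r[t]
        zt = z[t]
        ht = hc[t]
        dhc = dh * zt
        if relu:
            dah = dhc * (ht > zero)
        else:
            dah = dhc * (one - ht * ht)
        daz = dh * (ht - h) * zt * (one - zt)
        np.dot(dah, W, drh)
        dar = drh * h * rt * (one - rt)
        np.dot(dar, Wr, tmp1)
        np.dot(daz, Wz, tmp2)
        dar_all[t] = dar
        daz_all[t] = daz
        dah_all[t] = dah
        dh = dh * (one - zt) + drh * rt + tmp1 + tmp2
    return dh


_fwd_loop = _jit(_fwd_loop_impl)
_bwd_loop = _jit(_bwd_loop_impl)


class _LayerCache:
    __slots__ = ("X", "H_seq", "r", "z", "hc")

    def __init__(self, X, H_seq, r, z, hc):
        self.X, self.H_seq, self.r, self.z, self.hc = X, H_seq, r, z, hc


def layer_forward(X: np.ndarray, cell: GRUCellParams, relu: bool) -> _LayerCache:
    """Run one cell over a time-major batch ``X (T, B, D)``; h0 = 0."""
    T, B, D = X.shape
    H = cell.hidden_size
    dtype = X.dtype
    Ucat = np.concatenate([cell.U_r, cell.U_z, cell.U], axis=0)  # (3H, D)
    bcat = np.concatenate([cell.b_r, cell.b_z, cell.b_h])
    Xp = np.ascontiguousarray(X.reshape(T * B, D) @ Ucat.T + bcat).reshape(T, B, 3 * H)
    H_seq = np.zeros((T + 1, B, H), dtype=dtype)
    r = np.empty((T, B, H), dtype=dtype)
    z = np.empty((T, B, H), dtype=dtype)
    hc = np.empty((T, B, H), dtype=dtype)
    WrzT = np.ascontiguousarray(np.concatenate([cell.W_r.T, cell.W_z.T], axis=1))
    _fwd_loop(
        Xp,
        WrzT,
        np.ascontiguousarray(cell.W.T),
        H_seq,
        r,
        z,
        hc,
        relu,
        dtype.type(1.0),
    )
    return _LayerCache(X, H_seq, r, z, hc)


def layer_backward(
    cache: _LayerCache, cell: GRUCellParams, dH: np.ndarray, relu: bool
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Backprop one layer.  ``dH (T, B, H)`` is the gradient wrt the layer's
    hidden outputs; returns ``dX (T, B, D)`` and gradients in
    ``GRUCellParams.arrays()`` order."""
    T, B, H = dH.shape
    D = cache.X.shape[2]
    dtype = dH.dtype
    dar = np.empty((T, B, H), dtype=dtype)
    daz = np.empty((T, B, H), dtype=dtype)
    dah = np.empty((T, B, H), dtype=dtype)
    _bwd_loop(
        cache.H_seq, cache.r, cache.z, cache.hc,
        np.ascontiguousarray(dH),
        np.ascontiguousarray(cell.W_r),
        np.ascontiguousarray(cell.W_z),
        np.ascontiguousarray(cell.W),
        dar, daz, dah, relu, dtype.type(1.0),
    )
    # weight gradients as whole-sequence gemms (the per-step sums collapse)
    dar_f = dar.reshape(T * B, H)
    daz_f = daz.reshape(T * B, H)
    dah_f = dah.reshape(T * B, H)
    h_prev = cache.H_seq[:-1].reshape(T * B, H)
    rh = (cache.r * cache.H_seq[:-1]).reshape(T * B, H)
    X_f = cache.X.reshape(T * B, D)
    dWr = dar_f.T @ h_prev
    dWz = daz_f.T @ h_prev
    dW = dah_f.T @ rh
    dU_r = dar_f.T @ X_f
    dU_z = daz_f.T @ X_f
    dU = dah_f.T @ X_f
    dX = (dar_f @ cell.U_r + daz_f @ cell.U_z + dah_f @ cell.U).reshape(T, B, D)
    db_r = dar_f.sum(axis=0)
    db_z = daz_f.sum(axis=0)
    db_h = dah_f.sum(axis=0)
    return dX, [dU_r, dU_z, dU, dWr, dWz, dW, db_r, db_z, db_h]


class _StackCache:
    __slots__ = ("fwd", "bwd", "H_top_f", "H_top_b_rev")

    def __init__(self, fwd, bwd, H_top_f, H_top_b_rev):
        self.fwd, self.bwd = fwd, bwd
        self.H_top_f, self.H_top_b_rev = H_top_f, H_top_b_rev


def stack_forward(
    measurements: np.ndarray, params: NetworkParams, need_cache: bool = False
):
    """Run the full bidirectional stack over a batch.

    ``measurements`` is batch-major ``(B, T)``.  Returns
    ``(y_fwd (B, T), y_bwd (B, T), cache)`` where both estimates are in the
    input's time-index order; ``y_fwd[:, t]`` depends only on samples
    ``0..t`` and ``y_bwd[:, t]`` only on samples ``t..T-1``.
    """
    m = np.asarray(measurements, dtype=params.dtype)
    if m.ndim != 2:
        raise ValueError("measurements must be (B, T)")
    if not np.all(np.isfinite(m)):
        raise ValueError("measurements contain non-finite values")
    B, T = m.shape
    if T < 2:
        raise ValueError("window length must be >= 2")
    relu = params.activation == "relu"

    X_f = np.ascontiguousarray(m.T[:, :, None])          # (T, B, 1), time order
    X_b = np.ascontiguousarray(m.T[::-1][:, :, None])    # reversed time order
    fwd_caches, bwd_caches = [], []
    for fwd_cell, bwd_cell in params.layers:
        cf = layer_forward(X_f, fwd_cell, relu)
        cb = layer_forward(X_b, bwd_cell, relu)
        fwd_caches.append(cf)
        bwd_caches.append(cb)
        X_f = np.ascontiguousarray(cf.H_seq[1:])
        X_b = np.ascontiguousarray(cb.H_seq[1:])

    H_top_f = X_f                                        # (T, B, H)
    H_top_b_rev = X_b                                    # internally reversed time
    y_f = (H_top_f @ params.V_f + params.c_f[0]).T       # (B, T)
    y_b = (H_top_b_rev @ params.V_b + params.c_b[0]).T[:, ::-1]
    cache = (
        _StackCache(fwd_caches, bwd_caches, H_top_f, H_top_b_rev)
        if need_cache
        else None
    )
    return y_f, np.ascontiguousarray(y_b), cache


def stack_backward(
    params: NetworkParams,
    cache: _StackCache,
    dy_f: np.ndarray,
    dy_b: np.ndarray,
) -> list[np.ndarray]:
    """Backprop the whole stack.  ``dy_f, dy_b`` are ``(B, T)`` gradients of
    the loss wrt the two estimates (input time order).  Returns gradients in
    ``NetworkParams.arrays()`` order."""
    relu = params.activation == "relu"
    dy_f_t = np.ascontiguousarray(dy_f.T)                # (T, B)
    dy_b_rev = np.ascontiguousarray(dy_b[:, ::-1].T)     # internal (reversed) order

    dV_f = np.tensordot(dy_f_t, cache.H_top_f, axes=([0, 1], [0, 1]))
    dc_f = np.array([dy_f_t.sum()], dtype=params.dtype)
    dV_b = np.tensordot(dy_b_rev, cache.H_top_b_rev, axes=([0, 1], [0, 1]))
    dc_b = np.array([dy_b_rev.sum()], dtype=params.dtype)

    dH_f = dy_f_t[:, :, None] * params.V_f
    dH_b = dy_b_rev[:, :, None] * params.V_b
    layer_grads: list[list[np.ndarray]] = []
    for k in range(params.n_layers - 1, -1, -1):
        fwd_cell, bwd_cell = params.layers[k]
        dH_f, g_f = layer_backward(cache.fwd[k], fwd_cell, dH_f, relu)
        dH_b, g_b = layer_backward(cache.bwd[k], bwd_cell, dH_b, relu)
        layer_grads.append(g_f + g_b)

    grads: list[np.ndarray] = []
    for g in reversed(layer_grads):
        grads.extend(g)
    grads.extend([dV_f, dc_f, dV_b, dc_b])
    return grads


def init_params(
    n_layers: int,
    hidden_size: int,
    rng: np.random.Generator,
    activation: str = "relu",
    dtype=np.float32,
) -> NetworkParams:
    """Initialize a stack: Glorot-uniform input weights, orthogonal recurrent
    weights (candidate recurrence scaled by 0.5 to temper the unbounded ReLU
    state), zero biases, small random output heads."""

    def glorot(h, d):
        lim = np.sqrt(6.0 / (h + d))
        return rng.uniform(-lim, lim, size=(h, d)).astype(dtype)

    def orthogonal(h, gain=1.0):
        a = rng.standard_normal((h, h))
        q, _ = np.linalg.qr(a)
        return (gain * q).astype(dtype)

    layers = []
    for k in range(n_layers):
        d = 1 if k == 0 else hidden_size
        cells = []
        for _direction in range(2):
            cells.append(
                GRUCellParams(
                    U_r=glorot(hidden_size, d),
                    U_z=glorot(hidden_size, d),
                    U=glorot(hidden_size, d),
                    W_r=orthogonal(hidden_size),
                    W_z=orthogonal(hidden_size),
                    W=orthogonal(hidden_size, gain=0.5),
                )
            )
        layers.append((cells[0], cells[1]))
    scale = 1.0 / np.sqrt(hidden_size)
    return NetworkParams(
        layers=layers,
        V_f=(rng.standard_normal(hidden_size) * scale).astype(dtype),
        c_f=np.zeros(1, dtype=dtype),
        V_b=(rng.standard_normal(hidden_size) * scale).astype(dtype),
        c_b=np.zeros(1, dtype=dtype),
        activation=activation,
    )
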