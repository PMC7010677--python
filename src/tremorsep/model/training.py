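"""Training loop: shifted-target MSE minimised with Adam.

Both paths are trained against the one-sample-advanced voluntary ground
truth (the *shifted target*): the forward path thereby learns genuine
one-sample-ahead prediction, and training the backward path against the
same target keeps the two paths comparable under the same MSE criterion.
The returned parameters are those of the epoch with minimum validation
loss (best-validation checkpointing).
"""

from __future__ import annotations

import numpy as np

from ..synthetic_data import DatasetSplit, LabeledSegment
from .gru import NetworkParams, init_params, stack_backward, stack_forward
from .network import NetworkConfig

__all__ = ["train", "segments_to_arrays", "batched_forward", "AdamOptimizer"]


def segments_to_arrays(
    segments: list[LabeledSegment], dtype=np.float32
) -> tuple[np.ndarray, np.ndarray]:
    """Stack segments into ``(X, Y)`` arrays of shape ``(N, T)``:
    measurements and shifted targets."""
    if not segments:
        raise ValueError("empty segment list")
    X = np.stack([s.measurement for s in segments]).astype(dtype)
    Y = np.stack([s.shifted_target for s in segments]).astype(dtype)
    return X, Y


class AdamOptimizer:
    """Adam over a flat list of parameter arrays (updates in place)."""

    def __init__(self, arrays, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.arrays = arrays
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.t = 0

    def step(self, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for a, g, m, v in zip(self.arrays, grads, self.m, self.v):
            g = g.astype(a.dtype, copy=False)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            a -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def _two_path_loss(y_f, y_b, target):
    """Mean over batch/time of the squared residuals, averaged over the two
    paths; also returns the gradients wrt each path's output."""
    n = target.size
    rf = y_f - target
    rb = y_b - target
    loss = 0.5 * (np.mean(rf**2) + np.mean(rb**2))
    return loss, rf / n, rb / n


def batched_forward(params: NetworkParams, X: np.ndarray, chunk: int = 128):
    """Forward the stack over ``X (N, T)`` in memory-bounded chunks."""
    outs_f, outs_b = [], []
    for i in range(0, len(X), chunk):
        y_f, y_b, _ = stack_forward(X[i : i + chunk], params)
        outs_f.append(y_f)
        outs_b.append(y_b)
    return np.concatenate(outs_f), np.concatenate(outs_b)


def validation_loss(params: NetworkParams, X: np.ndarray, Y: np.ndarray) -> float:
    y_f, y_b = batched_forward(params, X)
    loss, _, _ = _two_path_loss(y_f, y_b, Y.astype(y_f.dtype))
    return float(loss)


def train(
    data: DatasetSplit,
    config: NetworkConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[NetworkParams, dict]:
    """Train the bidirectional stack on a subject-wise split dataset.

    Returns ``(params, history)`` where ``params`` are the weights at the
    epoch with minimum validation loss and ``history`` records per-epoch
    train and validation losses.  A fixed seed makes the run
    bit-reproducible.  Raises ``RuntimeError`` if the loss diverges.
    """
    if not data.train or not data.validation:
        raise ValueError("train and validation splits must be nonempty")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    dtype = np.dtype(config.dtype)
    X_tr, Y_tr = segments_to_arrays(data.train, dtype)
    X_va, Y_va = segments_to_arrays(data.validation, dtype)
    if X_tr.shape[1] != config.window:
        raise ValueError(
            f"segments of length {X_tr.shape[1]} but config.window={config.window}"
        )

    params = init_params(
        config.n_layers, config.hidden_size, rng, config.activation, dtype
    )
    opt = AdamOptimizer(params.arrays(), lr=config.learning_rate)

    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = params.copy()
    n = len(X_tr)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            xb, yb_t = X_tr[idx], Y_tr[idx]
            # overflow here means divergence, reported below rather than warned
            with np.errstate(over="ignore", invalid="ignore"):
                y_f, y_b, cache = stack_forward(xb, params, need_cache=True)
                loss, dy_f, dy_b = _two_path_loss(y_f, y_b, yb_t)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {epoch}, "
                    f"batch {n_batches} (lr={config.learning_rate})"
                )
            grads = stack_backward(params, cache, dy_f, dy_b)
            opt.step(grads)
            epoch_loss += float(loss)
            n_batches += 1
        history["train_loss"].append(epoch_loss / max(n_batches, 1))
        val = validation_loss(params, X_va, Y_va)
        history["val_loss"].append(val)
        if val < best_val:
            best_val = val
            best_params = params.copy()
    history["best_val_loss"] = float(best_val)
    return best_params, history
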