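"""Network-level contracts: configuration, batch inference, online
prediction and offline stitched estimation."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gru import GRUCellParams, NetworkParams, gru_cell_step, stack_forward

__all__ = [
    "NetworkConfig",
    "NetworkOutput",
    "network_forward",
    "OnlinePredictor",
    "predict_online",
    "estimate_offline",
]


@dataclass
class NetworkConfig:
    """Hyper-parameters of the separator network.

    The published full-scale geometry is 4 layers of 400 hidden features
    over 4 s (400-sample) windows at 100 Hz with Adam at learning rate
    1e-4; those are the defaults.  ``hidden_size`` is routinely reduced
    (e.g. to 64) for desk-scale experiments.  Batch size, epoch count and
    the float precision are training-side choices with no published value.
    """

    n_layers: int = 4
    hidden_size: int = 400
    window: int = 400
    rate_hz: float = 100.0
    learning_rate: float = 1e-4
    epochs: int = 50
    batch_size: int = 64
    seed: int = 0
    activation: str = "relu"
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.n_layers < 1 or self.hidden_size < 1:
            raise ValueError("n_layers and hidden_size must be >= 1")
        if self.window < 2:
            raise ValueError("window must be >= 2")
        if self.activation not in ("relu", "tanh"):
            raise ValueError("activation must be 'relu' or 'tanh'")


@dataclass
class NetworkOutput:
    """Paired per-window estimates of the voluntary component.

    ``forward_estimate[t]`` is the online path's one-sample-ahead estimate
    after seeing samples ``0..t``; ``backward_estimate`` comes from the
    backward-time recursion, re-aligned to input index order.  The two
    paths serve different applications and are never summed or averaged.
    """

    forward_estimate: np.ndarray
    backward_estimate: np.ndarray

    def __post_init__(self) -> None:
        if len(self.forward_estimate) != len(self.backward_estimate):
            raise ValueError("the two path estimates must have equal length")


def network_forward(measurement: np.ndarray, params: NetworkParams) -> NetworkOutput:
    """Run both paths of the stack over one measurement window.

    The forward estimate at index t depends only on ``measurement[0..t]``
    (causality); the backward estimate at index t only on
    ``measurement[t..T-1]``.
    """
    m = np.asarray(measurement, dtype=float)
    if m.ndim != 1:
        raise ValueError("measurement must be a 1-D window")
    y_f, y_b, _ = stack_forward(m[None, :], params)
    return NetworkOutput(forward_estimate=y_f[0], backward_estimate=y_b[0])


class OnlinePredictor:
    """Streaming one-sample-ahead voluntary-motion estimator.

    Feeds arriving samples through the forward-path cells only, carrying
    hidden state between calls; ``update(sample)`` returns the estimate of
    the voluntary component at the *next* sample time (a 10 ms horizon at
    100 Hz).  Equivalent to the last element of
    :func:`network_forward`'s forward estimate over the seen prefix.
    """

    def __init__(self, params: NetworkParams):
        self._params = params
        self._h = [
            np.zeros(fwd.hidden_size, dtype=params.dtype)
            for fwd, _ in params.layers
        ]
        self.n_seen = 0

    def update(self, sample: float) -> float:
        if not np.isfinite(sample):
            raise ValueError(f"non-finite sample at stream position {self.n_seen}")
        x = np.asarray([sample], dtype=self._params.dtype)
        relu = self._params.activation
        for k, (fwd_cell, _) in enumerate(self._params.layers):
            self._h[k] = gru_cell_step(x, self._h[k], fwd_cell, activation=relu)
            x = self._h[k]
        self.n_seen += 1
        return float(self._params.V_f @ self._h[-1] + self._params.c_f[0])


def predict_online(stream, params: NetworkParams) -> np.ndarray:
    """Apply :class:`OnlinePredictor` to a whole stream; element t is the
    estimate of the voluntary component at sample t + 1."""
    predictor = OnlinePredictor(params)
    return np.array([predictor.update(s) for s in np.asarray(stream, dtype=float)])


def estimate_offline(
    series: np.ndarray,
    params: NetworkParams,
    config: NetworkConfig,
    advance: int = 50,
) -> np.ndarray:
    """Stitched offline voluntary-motion estimate over a long series.

    A ``config.window``-sample window slides over the series in steps of
    ``advance`` samples; from each window only the backward path's first
    ``advance`` samples are kept (the refined end of the backward
    recursion), then the window advances and the estimation repeats.  The
    output covers the full input: the tail beyond the last regular window
    is completed from a final window aligned to the end of the series.
    """
    x = np.asarray(series, dtype=float)
    T = config.window
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    if len(x) < T:
        raise ValueError(f"series length {len(x)} is shorter than one window ({T})")
    if not 1 <= advance <= T:
        raise ValueError("advance must lie in [1, window]")
    n = len(x)

    starts = list(range(0, n - T + 1, advance))
    windows = np.stack([x[s : s + T] for s in starts])
    _, y_b, _ = stack_forward(windows, params)

    out = np.empty(n, dtype=float)
    covered = 0
    for i, s in enumerate(starts):
        keep = min(advance, n - s)
        out[s : s + keep] = y_b[i, :keep]
        covered = s + keep
    if covered < n:
        # final end-aligned window completes coverage
        tail_start = n - T
        _, y_tail, _ = stack_forward(x[tail_start:][None, :], params)
        out[covered:] = y_tail[0, covered - tail_start :]
    return out
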