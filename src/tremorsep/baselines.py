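"""Band-limited multiple Fourier linear combiner (FLC) tremor filters.

Classical comparison methods: tremor is modelled as a weighted bank of
sine/cosine pairs on a frequency grid covering the pathological band, with
weights adapted per sample by a least-mean-squares (LMS) rule on the
residual.  The voluntary estimate is the residual ``input - tremor``, so
the decomposition is exact by construction and strictly causal.

* **BMFLC** uses a fixed, predefined band.  When the tremor frequency is
  unknown a priori the band must cover the whole 3-14 Hz pathological
  range, which spreads adaptation over many grid components.
* **EBMFLC** periodically re-estimates the dominant tremor band from a
  short causal periodogram within 3-14 Hz and re-centers a narrower bank
  on it.  With band re-estimation disabled it reduces exactly to BMFLC.

The original combiner literature is not reproduced in detail here; the
implementation is a faithful-behaviour LMS combiner family with documented
defaults (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FLCConfig", "FLCState", "bmflc_filter", "ebmflc_filter", "PHT_BAND_HZ"]

PHT_BAND_HZ = (3.0, 14.0)


@dataclass(frozen=True)
class FLCConfig:
    """Configuration of the combiner bank.

    ``band_hz`` is the modelled tremor band (the fixed bank for BMFLC; the
    initial band, whose *width* is preserved on re-centering, for EBMFLC);
    ``delta_f_hz`` the grid step; ``mu`` the LMS adaptation gain;
    ``band_update_window`` the number of samples between EBMFLC band
    re-estimates.
    """

    band_hz: tuple[float, float] = PHT_BAND_HZ
    delta_f_hz: float = 0.5
    mu: float = 0.01
    adaptive_band: bool = False
    band_update_window: int = 100
    rate_hz: float = 100.0

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not 0 < lo < hi:
            raise ValueError("band must satisfy 0 < f_low < f_high")
        if self.delta_f_hz <= 0 or self.mu <= 0:
            raise ValueError("delta_f_hz and mu must be positive")
        if self.band_update_window < 1:
            raise ValueError("band_update_window must be >= 1")


@dataclass
class FLCState:
    """Adaptation state: one (sine, cosine) weight pair per grid frequency
    plus the current band estimate (EBMFLC)."""

    freqs_hz: np.ndarray
    weights: np.ndarray  # shape (2 * n_freqs,): [sine block, cosine block]
    band_hz: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.weights) != 2 * len(self.freqs_hz):
            raise ValueError("weight count must be 2 x number of grid frequencies")


def _grid(band_hz: tuple[float, float], delta_f: float) -> np.ndarray:
    lo, hi = band_hz
    n = int(np.floor((hi - lo) / delta_f + 1e-9)) + 1
    freqs = lo + delta_f * np.arange(n)
    if np.any(freqs <= 0):
        raise ValueError("frequency grid must not contain 0 Hz (DC belongs to voluntary)")
    return freqs


def _dominant_frequency(history: np.ndarray, rate_hz: float) -> float:
    """Causal periodogram argmax within the pathological 3-14 Hz band."""
    x = history - history.mean()
    spectrum = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / rate_hz)
    mask = (freqs >= PHT_BAND_HZ[0]) & (freqs <= PHT_BAND_HZ[1])
    if not mask.any() or spectrum[mask].max() == 0:
        return 0.5 * (PHT_BAND_HZ[0] + PHT_BAND_HZ[1])
    return float(freqs[mask][np.argmax(spectrum[mask])])


def _run_flc(series: np.ndarray, config: FLCConfig, adaptive: bool):
    x = np.asarray(series, dtype=float)
    if x.ndim != 1 or len(x) == 0:
        raise ValueError("series must be a nonempty 1-D array")
    freqs = _grid(config.band_hz, config.delta_f_hz)
    band = config.band_hz
    width = band[1] - band[0]
    w_sin = np.zeros(len(freqs))
    w_cos = np.zeros(len(freqs))
    tremor_est = np.empty_like(x)
    two_pi_t = 2.0 * np.pi / config.rate_hz
    hist_len = 2 * config.band_update_window

    for t in range(len(x)):
        if adaptive and t > 0 and t % config.band_update_window == 0:
            history = x[max(0, t - hist_len) : t]
            if len(history) >= 32:
                f_dom = _dominant_frequency(history, config.rate_hz)
                lo = min(max(f_dom - width / 2.0, PHT_BAND_HZ[0]), PHT_BAND_HZ[1] - width)
                new_band = (lo, lo + width)
                if abs(new_band[0] - band[0]) > 1e-12:
                    band = new_band
                    freqs = _grid(band, config.delta_f_hz)
                    w_sin = np.zeros(len(freqs))
                    w_cos = np.zeros(len(freqs))
        arg = two_pi_t * freqs * t
        s = np.sin(arg)
        c = np.cos(arg)
        est = w_sin @ s + w_cos @ c
        e = x[t] - est
        w_sin = w_sin + 2.0 * config.mu * e * s
        w_cos = w_cos + 2.0 * config.mu * e * c
        tremor_est[t] = est

    voluntary_est = x - tremor_est
    state = FLCState(
        freqs_hz=freqs, weights=np.concatenate([w_sin, w_cos]), band_hz=band
    )
    return voluntary_est, tremor_est, state


def bmflc_filter(series, config: FLCConfig):
    """Fixed-band combiner.  Returns ``(voluntary_estimate, tremor_estimate)``
    with ``voluntary + tremor == input`` elementwise."""
    if config.adaptive_band:
        raise ValueError("bmflc_filter requires adaptive_band=False")
    v, s, _ = _run_flc(series, config, adaptive=False)
    return v, s


def ebmflc_filter(series, config: FLCConfig):
    """Adaptive-band combiner: the bank re-centers on the dominant spectral
    peak found causally within 3-14 Hz every ``band_update_window`` samples.
    With ``adaptive_band=False`` it reduces exactly to :func:`bmflc_filter`."""
    v, s, _ = _run_flc(series, config, adaptive=config.adaptive_band)
    return v, s
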