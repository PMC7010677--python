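"""Quantitative metrics, spectrotemporal diagnostics and comparison
statistics.

* MSE of an estimated voluntary component against its ground truth
  (``MSE = (1/T) sum_t (gt(t) - est(t))^2``), plus the endpoint errors that
  matter for deployment: the forward path's *last* sample (online use) and
  the backward path's *first* sample (offline use).
* A sliding-FFT power-spectral-density matrix (window 50, overlap 45 by
  default) for visual/spectral inspection.
* Population-level spectral comparison of inputs vs outputs per frequency
  bin (D'Agostino-Pearson normality check, two-sample Z-test, 1.96-sigma
  confidence bands), excluding the 0 Hz bin.
* Method comparison: one-way ANOVA across methods, pairwise Z-tests (raw
  and Bonferroni-adjusted), 95% CIs, and percent improvement of the best
  method over each baseline.

"Normalized MSE" here means the MSE evaluated on signals on the [0, 1]
pipeline scale (on pipeline data it coincides with the plain MSE); a
power-normalized alternative is provided as :func:`relative_mse`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st
from statsmodels.stats.weightstats import ztest as _sm_ztest

__all__ = [
    "EvalRecord",
    "SpectralSummary",
    "MethodComparison",
    "mse",
    "relative_mse",
    "endpoint_errors",
    "sliding_psd",
    "spectral_population_compare",
    "compare_methods",
]

Z_95 = 1.96


@dataclass(frozen=True)
class EvalRecord:
    """Per-segment errors of one method on one split."""

    segment_mse: float
    last_sample_forward_error: float
    first_sample_backward_error: float
    method: str = ""
    split: str = ""

    def __post_init__(self) -> None:
        if min(
            self.segment_mse,
            self.last_sample_forward_error,
            self.first_sample_backward_error,
        ) < 0:
            raise ValueError("errors must be nonnegative")


@dataclass
class SpectralSummary:
    """Per-frequency population statistics of input/output spectra.

    CI half-widths equal ``1.96 * sd / sqrt(n)``; the 0 Hz bin is excluded.
    """

    freqs_hz: np.ndarray
    input_mean: np.ndarray
    input_sd: np.ndarray
    output_mean: np.ndarray
    output_sd: np.ndarray
    input_ci_halfwidth: np.ndarray
    output_ci_halfwidth: np.ndarray
    p_values: np.ndarray
    input_normality_p: np.ndarray
    output_normality_p: np.ndarray
    n: int


@dataclass
class MethodComparison:
    """ANOVA + pairwise statistics across methods.

    ``improvement_pct[m] = (mean_m - mean_ref) / mean_m * 100`` for each
    non-reference method m (positive when the reference is better).
    """

    methods: list
    means: dict
    ci_halfwidth: dict
    anova_p: float
    pairwise_p: dict
    pairwise_p_bonferroni: dict
    reference: str
    improvement_pct: dict


def mse(estimate, ground_truth, normalized: bool = False) -> float:
    """Mean squared error between an estimate and its ground truth.

    With ``normalized=True`` the inputs are checked to lie on the [0, 1]
    pipeline scale; the value is the same mean of squared residuals (the
    normalization lives in the signal scale, not in the formula).
    """
    a = np.asarray(estimate, dtype=float)
    b = np.asarray(ground_truth, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 1:
        raise ValueError("need at least one sample")
    if normalized:
        tol = 1e-9
        if b.min() < -tol or b.max() > 1 + tol:
            raise ValueError("normalized=True expects signals on the [0, 1] scale")
    return float(np.mean((a - b) ** 2))


def relative_mse(estimate, ground_truth) -> float:
    """MSE divided by the ground truth's mean power (scale-free variant)."""
    b = np.asarray(ground_truth, dtype=float)
    power = float(np.mean(b**2))
    if power == 0:
        raise ValueError("ground truth has zero power")
    return mse(estimate, ground_truth) / power


def endpoint_errors(outputs, targets) -> tuple[float, float]:
    """Mean squared endpoint errors over a batch of network outputs.

    Returns ``(forward last-sample error, backward first-sample error)``:
    the squared residual at index T-1 of the forward path and at index 0 of
    the backward path, averaged over the batch.
    """
    outputs = list(outputs)
    targets = list(targets)
    if not outputs or len(outputs) != len(targets):
        raise ValueError("need a nonempty, aligned batch")
    last_sq, first_sq = [], []
    for out, tgt in zip(outputs, targets):
        tgt = np.asarray(tgt, dtype=float)
        if len(out.forward_estimate) != len(tgt):
            raise ValueError("output/target length mismatch")
        last_sq.append((out.forward_estimate[-1] - tgt[-1]) ** 2)
        first_sq.append((out.backward_estimate[0] - tgt[0]) ** 2)
    return float(np.mean(last_sq)), float(np.mean(first_sq))


def sliding_psd(
    series,
    window: int = 50,
    overlap: int = 45,
    rate_hz: float = 100.0,
    taper: str = "rectangular",
):
    """Sliding-FFT power spectral density matrix.

    Columns are windows starting at 0, hop, 2*hop, ... with
    ``hop = window - overlap``; rows are rfft frequency bins.  Entries are
    squared FFT magnitudes scaled to amplitude^2/Hz (one-sided).  Returns
    ``(freqs_hz, times_s, psd)`` with ``psd`` of shape
    ``(n_freqs, n_windows)``.
    """
    x = np.asarray(series, dtype=float)
    if not 0 <= overlap < window:
        raise ValueError("overlap must satisfy 0 <= overlap < window")
    if len(x) < window:
        raise ValueError(f"series length {len(x)} shorter than window {window}")
    hop = window - overlap
    n_cols = (len(x) - window) // hop + 1
    if taper == "rectangular":
        win = np.ones(window)
    elif taper == "hann":
        win = np.hanning(window)
    else:
        raise ValueError("taper must be 'rectangular' or 'hann'")
    starts = hop * np.arange(n_cols)
    frames = np.stack([x[s : s + window] * win for s in starts])
    spec = np.fft.rfft(frames, axis=1)
    scale = 1.0 / (rate_hz * np.sum(win**2))
    psd = (np.abs(spec) ** 2 * scale).T
    # one-sided: double everything except DC (and Nyquist for even windows)
    if window % 2 == 0:
        psd[1:-1] *= 2
    else:
        psd[1:] *= 2
    freqs = np.fft.rfftfreq(window, d=1.0 / rate_hz)
    times = (starts + window / 2.0) / rate_hz
    return freqs, times, psd


def _spectra(group: np.ndarray, rate_hz: float):
    mags = np.abs(np.fft.rfft(group, axis=1))
    freqs = np.fft.rfftfreq(group.shape[1], d=1.0 / rate_hz)
    return freqs[1:], mags[:, 1:]  # exclude the 0 Hz bin


def _two_sample_z(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample (unpaired, unequal-variance) Z-test p-value."""
    if np.std(a) == 0 and np.std(b) == 0:
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    _, p = _sm_ztest(a, b, usevar="unequal")
    return float(p)


def spectral_population_compare(
    inputs, outputs, rate_hz: float = 100.0
) -> SpectralSummary:
    """Compare the per-frequency FFT-magnitude populations of two signal
    groups (e.g. network inputs vs outputs).

    Normality of each population at each frequency is checked first with
    the D'Agostino-Pearson test; the group difference is then assessed per
    frequency with a two-sample Z-test, and 95% confidence half-widths are
    ``1.96 * sd / sqrt(n)``.
    """
    X = np.asarray(inputs, dtype=float)
    Y = np.asarray(outputs, dtype=float)
    if X.shape != Y.shape:
        raise ValueError("input and output groups must have identical shapes")
    n = X.shape[0]
    if n < 20:
        raise ValueError("need n >= 20 sequences per group for the normality test")
    freqs, mag_in = _spectra(X, rate_hz)
    _, mag_out = _spectra(Y, rate_hz)

    def _normality(mags):
        with np.errstate(all="ignore"):
            return np.array(
                [
                    _st.normaltest(col).pvalue if np.std(col) > 0 else np.nan
                    for col in mags.T
                ]
            )

    p_values = np.array(
        [_two_sample_z(mag_in[:, j], mag_out[:, j]) for j in range(len(freqs))]
    )
    return SpectralSummary(
        freqs_hz=freqs,
        input_mean=mag_in.mean(axis=0),
        input_sd=mag_in.std(axis=0, ddof=1),
        output_mean=mag_out.mean(axis=0),
        output_sd=mag_out.std(axis=0, ddof=1),
        input_ci_halfwidth=Z_95 * mag_in.std(axis=0, ddof=1) / np.sqrt(n),
        output_ci_halfwidth=Z_95 * mag_out.std(axis=0, ddof=1) / np.sqrt(n),
        p_values=p_values,
        input_normality_p=_normality(mag_in),
        output_normality_p=_normality(mag_out),
        n=n,
    )


def compare_methods(
    errors_by_method: dict, reference: str | None = None
) -> MethodComparison:
    """Compare per-segment error samples across methods.

    All methods must be evaluated on the identical segments (equal sample
    counts, same order).  ``reference`` names the method improvements are
    computed for; by default the method with the lowest mean error.
    Pairwise Z-test p-values are reported raw and Bonferroni-adjusted (the
    adjustment is labelled; no correction is silently applied).
    """
    methods = list(errors_by_method)
    if len(methods) < 2:
        raise ValueError("need at least two methods")
    samples = {m: np.asarray(errors_by_method[m], dtype=float) for m in methods}
    n = len(samples[methods[0]])
    if n < 20:
        raise ValueError("need at least 20 error samples per method")
    if any(len(s) != n for s in samples.values()):
        raise ValueError("methods must be evaluated on identical segment counts")

    means = {m: float(s.mean()) for m, s in samples.items()}
    ci = {m: float(Z_95 * s.std(ddof=1) / np.sqrt(n)) for m, s in samples.items()}
    anova_p = float(_st.f_oneway(*samples.values()).pvalue)

    pairs = [(a, b) for i, a in enumerate(methods) for b in methods[i + 1 :]]
    pairwise = {
        (a, b): _two_sample_z(samples[a], samples[b]) for a, b in pairs
    }
    bonf = {k: min(1.0, p * len(pairs)) for k, p in pairwise.items()}

    if reference is None:
        reference = min(means, key=means.get)
    if reference not in samples:
        raise ValueError(f"unknown reference method {reference!r}")
    improvement = {
        m: (
            float((means[m] - means[reference]) / means[m] * 100.0)
            if means[m] != 0
            else 0.0
        )
        for m in methods
        if m != reference
    }
    return MethodComparison(
        methods=methods,
        means=means,
        ci_halfwidth=ci,
        anova_p=anova_p,
        pairwise_p=pairwise,
        pairwise_p_bonferroni=bonf,
        reference=reference,
        improvement_pct=improvement,
    )
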