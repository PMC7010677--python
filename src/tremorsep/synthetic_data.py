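"""Pseudo-synthesized action-tremor data with exact voluntary ground truth.

Clinical action-tremor recordings have no observable ground truth for the
voluntary component, so training and scoring use *pseudo-synthesized*
mixtures: a synthetic voluntary sinusoid (random amplitude, frequency and
phase) added to a (here: simulated) static pathological-tremor signal.
The voluntary part is exactly known, which makes supervised training and
inverse evaluation possible.

Conventions
-----------
* voluntary component ``v(t) = a sin(2 pi f t + phi)`` with
  ``a ~ U(0, 0.25)``, ``f ~ U(0, 3)`` Hz, ``phi ~ U(0, pi)``, so
  ``v in [-0.25, 0.25]``;
* static tremor min-max scaled per recording into ``[0, 0.5]``;
* measurement ``m = v + 0.25 + s`` lies in ``[0, 1]`` (the fixed ``+0.25``
  offset reconciles the three printed ranges and is stored with every
  segment so the raw voluntary component stays recoverable);
* training targets are the one-sample-advanced voluntary component on the
  same ``[0, 1]`` pipeline scale, which teaches one-sample-ahead
  prediction;
* train/validation/test splits partition *subjects* (no subject appears
  in two splits), mirroring a 60/20/20 subject-wise protocol.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as _sps

from .signal_io import scale_affine

__all__ = [
    "VOLUNTARY_OFFSET",
    "VoluntaryParams",
    "TremorSimParams",
    "LabeledSegment",
    "DatasetSplit",
    "sample_voluntary_params",
    "generate_voluntary",
    "simulate_static_tremor",
    "mix_components",
    "build_dataset",
]

#: Fixed offset added to the voluntary component inside every mixture so the
#: sum of voluntary ([-0.25, 0.25]) and tremor ([0, 0.5]) lands in [0, 1].
VOLUNTARY_OFFSET = 0.25

PHT_BAND_HZ = (3.0, 14.0)


@dataclass(frozen=True)
class VoluntaryParams:
    """Amplitude (unitless), frequency (Hz) and phase (rad) of one voluntary
    sinusoid; supports are the closed intervals the generator draws from."""

    a: float
    f: float
    phi: float

    def __post_init__(self) -> None:
        if not 0 <= self.a <= 0.25:
            raise ValueError("amplitude a must lie in [0, 0.25]")
        if not 0 <= self.f <= 3:
            raise ValueError("frequency f must lie in [0, 3] Hz")
        if not 0 <= self.phi <= np.pi:
            raise ValueError("phase phi must lie in [0, pi]")


@dataclass(frozen=True)
class TremorSimParams:
    """Configuration of the static-tremor simulator.

    The simulator is a synthetic stand-in for clinic rest/postural tremor
    recordings (which are confidential): a pseudo-rhythmic carrier whose
    amplitude follows a log random walk (waxing/waning), whose frequency
    wanders slowly around ``center_hz``, plus broadband noise, band-passed
    to ``band_hz`` and min-max scaled to [0, 0.5].  Defaults place the
    dominant power near 5 Hz inside the 3-14 Hz pathological band.
    """

    band_hz: tuple[float, float] = (4.0, 8.0)
    center_hz: float = 5.0
    amp_drift_rate: float = 0.03
    freq_jitter_hz: float = 0.5
    noise_floor: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not (PHT_BAND_HZ[0] <= lo < hi <= PHT_BAND_HZ[1]):
            raise ValueError(
                f"band_hz must satisfy {PHT_BAND_HZ[0]} <= low < high <= {PHT_BAND_HZ[1]}"
            )
        if not (lo <= self.center_hz <= hi):
            raise ValueError("center_hz must lie inside band_hz")
        if min(self.amp_drift_rate, self.freq_jitter_hz, self.noise_floor) < 0:
            raise ValueError("rates and noise levels must be >= 0")


@dataclass
class LabeledSegment:
    """One fixed-length measurement window with its voluntary ground truth.

    ``voluntary_gt`` and ``shifted_target`` are on the [0, 1] pipeline
    scale (raw voluntary + ``offset``); ``shifted_target[k] ==``
    the pipeline-scale voluntary component at sample ``k + 1``, so
    ``shifted_target[k] == voluntary_gt[k + 1]`` for ``k < T - 1``.
    """

    measurement: np.ndarray
    voluntary_gt: np.ndarray
    shifted_target: np.ndarray
    subject_id: str
    tremor: np.ndarray | None = None
    offset: float = VOLUNTARY_OFFSET
    rate_hz: float = 100.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        T = len(self.measurement)
        if not (len(self.voluntary_gt) == len(self.shifted_target) == T):
            raise ValueError("measurement, voluntary_gt and shifted_target lengths differ")


@dataclass
class DatasetSplit:
    """Subject-wise train/validation/test partition of labeled segments."""

    train: list[LabeledSegment]
    validation: list[LabeledSegment]
    test: list[LabeledSegment]

    def __post_init__(self) -> None:
        subjects = [
            {seg.subject_id for seg in part}
            for part in (self.train, self.validation, self.test)
        ]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = subjects[i] & subjects[j]
                if overlap:
                    raise ValueError(f"subjects {sorted(overlap)} appear in two splits")

    def subjects(self) -> tuple[set, set, set]:
        return (
            {s.subject_id for s in self.train},
            {s.subject_id for s in self.validation},
            {s.subject_id for s in self.test},
        )


def sample_voluntary_params(rng: np.random.Generator) -> VoluntaryParams:
    """Draw independent a ~ U(0, 0.25), f ~ U(0, 3) Hz, phi ~ U(0, pi)."""
    return VoluntaryParams(
        a=float(rng.uniform(0.0, 0.25)),
        f=float(rng.uniform(0.0, 3.0)),
        phi=float(rng.uniform(0.0, np.pi)),
    )


def generate_voluntary(params: VoluntaryParams, n: int, rate_hz: float) -> np.ndarray:
    """Evaluate ``a sin(2 pi f k / rate_hz + phi)`` for k = 0..n-1."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not rate_hz > 0:
        raise ValueError("rate_hz must be positive")
    t = np.arange(n) / rate_hz
    return params.a * np.sin(2.0 * np.pi * params.f * t + params.phi)


def simulate_static_tremor(
    params: TremorSimParams,
    n: int,
    rate_hz: float,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate a nonstationary static-tremor series scaled to [0, 0.5].

    A carrier at ``center_hz`` with slow sinusoidal frequency wander
    (amplitude ``freq_jitter_hz``) and a log-random-walk amplitude envelope
    (step ``amp_drift_rate`` per sample) is summed with white noise of
    standard deviation ``noise_floor`` (relative to unit carrier
    amplitude), band-passed to ``band_hz`` with a zero-phase Butterworth
    filter, then min-max scaled to [0, 0.5].
    """
    if n < 2 * rate_hz:
        raise ValueError("need at least 2 seconds of signal so spectra are estimable")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    # slow frequency wander: ~0.1 Hz sinusoid with random phase
    t = np.arange(n) / rate_hz
    wander_phase = rng.uniform(0, 2 * np.pi)
    f_inst = params.center_hz + params.freq_jitter_hz * np.sin(
        2 * np.pi * 0.1 * t + wander_phase
    )
    lo, hi = params.band_hz
    f_inst = np.clip(f_inst, lo, hi)
    phase = 2 * np.pi * np.cumsum(f_inst) / rate_hz + rng.uniform(0, 2 * np.pi)

    log_env = np.cumsum(rng.normal(0.0, params.amp_drift_rate, size=n))
    log_env -= log_env.mean()
    log_env = np.clip(log_env, -2.5, 2.5)
    envelope = np.exp(log_env)

    raw = envelope * np.sin(phase) + params.noise_floor * rng.standard_normal(n)

    nyq = rate_hz / 2.0
    sos = _sps.butter(4, [lo / nyq, hi / nyq], btype="band", output="sos")
    shaped = _sps.sosfiltfilt(sos, raw)

    scaled, _ = scale_affine(shaped, 0.0, 0.5)
    return scaled


def mix_components(voluntary: np.ndarray, tremor: np.ndarray) -> np.ndarray:
    """Additively mix voluntary and tremor onto the [0, 1] pipeline scale.

    ``measurement[k] = voluntary[k] + VOLUNTARY_OFFSET + tremor[k]``; with
    voluntary in [-0.25, 0.25] and tremor in [0, 0.5] the result is
    guaranteed to lie in [0, 1].
    """
    v = np.asarray(voluntary, dtype=float)
    s = np.asarray(tremor, dtype=float)
    if v.shape != s.shape:
        raise ValueError(f"length mismatch: voluntary {v.shape} vs tremor {s.shape}")
    tol = 1e-9
    if v.min() < -0.25 - tol or v.max() > 0.25 + tol:
        raise ValueError("voluntary component must lie in [-0.25, 0.25]")
    if s.min() < -tol or s.max() > 0.5 + tol:
        raise ValueError("tremor component must lie in [0, 0.5]")
    return v + VOLUNTARY_OFFSET + s


def _largest_remainder_counts(n: int, fracs: tuple[float, ...]) -> list[int]:
    """Apportion n items to fractions by largest-remainder rounding."""
    quotas = [n * f for f in fracs]
    counts = [int(np.floor(q)) for q in quotas]
    remainder = n - sum(counts)
    order = np.argsort([c - q for c, q in zip(counts, quotas)])  # largest remainder first
    for k in range(remainder):
        counts[order[k]] += 1
    return counts


def _subject_segments(
    subject_id: str,
    n_segments: int,
    window: int,
    config: TremorSimParams,
    rate_hz: float,
    rng: np.random.Generator,
    windows_per_recording: int = 5,
) -> list[LabeledSegment]:
    """Synthesize one subject: 20 s recordings cut into non-overlapping windows."""
    segments: list[LabeledSegment] = []
    n_rec = int(np.ceil(n_segments / windows_per_recording))
    for r in range(n_rec):
        n_samples = window * windows_per_recording
        vparams = sample_voluntary_params(rng)
        voluntary = generate_voluntary(vparams, n_samples + 1, rate_hz)
        tremor = simulate_static_tremor(config, n_samples, rate_hz, rng=rng)
        measurement = mix_components(voluntary[:-1], tremor)
        gt_scaled = voluntary + VOLUNTARY_OFFSET
        for w in range(windows_per_recording):
            if len(segments) == n_segments:
                break
            s = w * window
            segments.append(
                LabeledSegment(
                    measurement=measurement[s : s + window],
                    voluntary_gt=gt_scaled[s : s + window],
                    shifted_target=gt_scaled[s + 1 : s + window + 1],
                    subject_id=subject_id,
                    tremor=tremor[s : s + window],
                    offset=VOLUNTARY_OFFSET,
                    rate_hz=rate_hz,
                    provenance={"recording": r, "window": w, "params": vparams},
                )
            )
    return segments


def build_dataset(
    n_subjects: int,
    segments_per_subject: int,
    window: int,
    config: TremorSimParams | None = None,
    split_fracs: tuple[float, float, float] = (0.6, 0.2, 0.2),
    rng: np.random.Generator | int | None = None,
    rate_hz: float = 100.0,
) -> DatasetSplit:
    """Build a subject-wise split pseudo-synthesized dataset.

    Each synthetic subject contributes ``segments_per_subject`` windows cut
    from 20 s recordings (5 windows of 4 s each at the default rates); every
    recording gets a fresh voluntary-parameter draw and an independent
    tremor simulation.  Subjects are shuffled and apportioned to the three
    splits by largest-remainder rounding of ``split_fracs``.  Fixing the
    master seed makes the whole dataset bit-reproducible.
    """
    if n_subjects < 5:
        raise ValueError("need at least 5 subjects so every split is nonempty")
    if window < 2:
        raise ValueError("window must be >= 2")
    if abs(sum(split_fracs) - 1.0) > 1e-9:
        raise ValueError(f"split fractions must sum to 1, got {split_fracs}")
    if config is None:
        config = TremorSimParams()
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)

    counts = _largest_remainder_counts(n_subjects, split_fracs)
    order = rng.permutation(n_subjects)
    split_of_subject = np.empty(n_subjects, dtype=int)
    pos = 0
    for split_idx, c in enumerate(counts):
        split_of_subject[order[pos : pos + c]] = split_idx
        pos += c

    parts: tuple[list, list, list] = ([], [], [])
    for i in range(n_subjects):
        subject_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        segs = _subject_segments(
            f"S{i:03d}", segments_per_subject, window, config, rate_hz, subject_rng
        )
        parts[split_of_subject[i]].extend(segs)
    return DatasetSplit(train=parts[0], validation=parts[1], test=parts[2])
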