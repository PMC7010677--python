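# tremorsep

Separation of **voluntary hand motion** from **pathological hand tremor
(PHT)** in accelerometer time series, with one-sample-ahead prediction of
the voluntary component.

People with Parkinson's disease (PD) or essential tremor (ET) produce
hand-motion signals in which the intended movement (slow, < ~3 Hz) is
superimposed with an involuntary, pseudo-rhythmic 3–14 Hz oscillation.
Assistive and rehabilitation robots need the voluntary part with zero or
negative phase lag — a 10–20 ms delay can destabilise a high-gain control
loop.  `tremorsep` is aimed at researchers in biomedical signal
processing and rehabilitation robotics who need (a) an exactly supervised
testbed for tremor-filtering methods and (b) a predictive, data-driven
separator to compare against classical adaptive filters.

## What is inside

* **`tremorsep.synthetic_data`** — *pseudo-synthesized action tremor*:
  a voluntary sinusoid `v(t) = a sin(2πft + φ)` with
  `a ~ U(0, 0.25)`, `f ~ U(0, 3)` Hz, `φ ~ U(0, π)`, added to a
  simulated static tremor signal (nonstationary, dominant power near
  5 Hz, scaled per recording to `[0, 0.5]`), giving measurements on a
  `[0, 1]` scale with the voluntary ground truth exactly known.
  Subject-wise 60/20/20 train/validation/test splits.
* **`tremorsep.model`** — a 4-layer **bidirectional GRU** stack with
  fully separated paths (no mixing matrix).  Cells follow

      r = σ(U_r x + W_r h′),  z = σ(U_z x + W_z h′),
      h̃ = ReLU(U x + W (r ⊙ h′)),  h = (1 − z) ⊙ h′ + z ⊙ h̃

  with a linear head per path.  Training minimises the MSE against the
  **one-sample-shifted** voluntary ground truth, which makes the causal
  forward path a one-step-ahead (10 ms at 100 Hz) predictor; the backward
  path serves offline estimation via an advance-50/keep-50 stitching
  rule.  The engine (forward + backprop-through-time + Adam) is numpy
  with numba-compiled recurrences.
* **`tremorsep.baselines`** — band-limited multiple Fourier linear
  combiners: fixed-band **BMFLC** and adaptive-band **EBMFLC** (LMS
  adaptation of a sine/cosine bank; exact, causal decomposition).
* **`tremorsep.evaluation`** — segment MSE `(1/T) Σ (m_v^GT − ŷ_v)²`,
  endpoint errors (forward last sample / backward first sample),
  sliding-FFT PSD (window 50, overlap 45), per-frequency Z-test spectral
  comparison with 1.96·σ/√n confidence bands, ANOVA + pairwise method
  comparison with percent improvements.
* **`tremorsep.signal_io`** — CSV/TSV recordings, anti-aliased zero-phase
  resampling (e.g. 1500 → 100 Hz), min-max scaling, windowing; HDF5
  containers for datasets and checkpoints; `tremorsep` CLI.

See `docs/methods.md` for the model, its assumptions, and the design
choices.

## Worked example

```python
import numpy as np
from tremorsep import benchmark as B
from tremorsep.evaluation import compare_methods
from tremorsep.model import train

config = B.benchmark_config(seed=0)          # 4 layers x 64 hidden, 4 s windows
data = B.benchmark_dataset(seed=0)           # 30 subjects x 60 segments
params, history = train(data, config, rng=np.random.default_rng(1))

results = B.evaluate_methods(params, data, split="test")
cmp = compare_methods(results["errors"], reference="bigru")
print({k: round(v, 5) for k, v in cmp.means.items()})
print({k: round(v, 2) for k, v in cmp.improvement_pct.items()})
```

which prints (≈17 min of training on one CPU core):

```
{'bigru': 0.00064, 'ebmflc': 0.09266, 'bmflc': 0.16356}
{'ebmflc': 99.31, 'bmflc': 99.61}
```

Read: on 360 held-out test segments the trained network estimates the
voluntary component with a normalized MSE of ~7e-4 on the `[0, 1]`
pipeline scale, versus ~0.09 (EBMFLC) and ~0.16 (BMFLC) — the combiners
cannot assign the tremor channel's DC level and leave tremor residue,
while the network removes both; the "improvement" rows are the percent
reduction in mean normalized MSE when moving from each baseline to the
network.  Training history, endpoint errors, spectral damping and the
behavioural probes are all exposed via `tremorsep.benchmark.run_benchmark`.

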