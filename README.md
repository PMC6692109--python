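# kymotrace

Automated extraction of particle tracks from **kymographs** — the
space–time images (rows = time, columns = position along a path) used
throughout cell biology to quantify intracellular transport.  Moving
particles appear in a kymograph as sloped, frequently crossing and
blinking lines; `kymotrace` turns those lines back into per-particle
trajectories and kinematic statistics.

The package contains:

- **`kymotrace.simgen`** — seeded simulators for unidirectional
  (constant-direction) and bidirectional (stopping / reversing) particle
  movies with full ground truth, including signal gaps and Gaussian
  noise calibrated to a target signal-to-noise ratio (SNR =
  mean signal / mean background on the noiseless signal mask).
- **`kymotrace.nets`** — a self-contained NumPy deep-learning stack
  (convolution, batch norm, pooling, Adam) with a U-Net used for three
  trackness-segmentation/decision modules and an encoder classifier
  that routes kymographs to the uni- or bidirectional pipeline.
  Networks train from scratch on simulated data; a `width_multiplier`
  scales all feature widths so reduced-scale models train on one CPU.
- **`kymotrace.tracer`** — the tracing engine: binarize the trackness
  map, thin to a 1-px skeleton, prune short spurs, trim same-row ends,
  find track seeds with a hit-miss transform, walk each seed forward in
  time resolving branch points with the decision module, then
  consolidate overlapping candidates and link short fragment gaps.
- **`kymotrace.wavelet_baseline`** — a classical comparator: stationary
  Haar-wavelet trackness, skeletonization, and linear-extrapolation
  linking.
- **`kymotrace.benchmark`** — track-level recall / precision / F1
  (best-single-prediction matching at 3.2 px Euclidean tolerance), gap
  resolution and crossing resolution scores, with set-level medians.
- **`kymotrace.kinematics`** — per-track and per-kymograph speed,
  displacement, directionality, pause and reversal statistics.
- **`kymotrace.kymio`** — multi-page TIFF I/O, kymograph extraction
  along user paths from movies, track CSV export, and overlay rendering.

## Command-line usage

Generate a seeded synthetic fixture set:

```
$ kymotrace simulate --mode bi --n 2 --seed 3 --out fixtures/
wrote 2 sample(s) to fixtures
```

This writes `bi_00003_kymo.tif`, `bi_00003_truth.csv` (columns
`track_id,frame,position,visible`), the same for seed 4, and a
`manifest.json` recording the measured SNR and noise sigma per sample.

Train the four network modules into one bundle (reduced width trains in
minutes per module on a single CPU; larger settings improve accuracy):

```
$ kymotrace train --module class    --out models.npz
$ kymotrace train --module uniseg   --out models.npz
$ kymotrace train --module biseg    --out models.npz
$ kymotrace train --module decision --out models.npz
```

Trace a kymograph TIFF and benchmark engines on simulated sets:

```
$ kymotrace trace --input fixtures/bi_00003_kymo.tif --engine nn \
      --models models.npz --out traced/
$ kymotrace benchmark --engine oracle --set bi --n 2 --seed 0 --out bench/
wrote bench/benchmark.csv and bench/benchmark.json
median F1 1.000  gap 1.000  crossing 1.000
```

`trace` writes `tracks.csv`, a kinematic `summary.csv`, an
`overlay.png` of tracks on the kymograph, and a `manifest.json`.
`benchmark --engine oracle` runs the tracing engine on noise-free
ground-truth skeletons with a ground-truth decision stub — a closure
test of the engine itself, which scores ≈1.0 on all three metrics.

`kymotrace summarize` recomputes kinematics from any tracks CSV.

## Python usage

```python
import numpy as np
from kymotrace.simgen import BiSimConfig, simulate_bidirectional
from kymotrace.wavelet_baseline import trace_wavelet
from kymotrace.benchmark import benchmark_sample

sample = simulate_bidirectional(BiSimConfig(), seed=7, render_movie=False)
tracks = trace_wavelet(sample.kymograph, seed=7)
print(benchmark_sample(sample, tracks))
```

## Reproducing results

- `python scripts/acceptance.py --seed 1 --out results/acceptance.json`
  recomputes the two simulator calibration targets (mean SNR over 10
  unidirectional and 10 bidirectional samples; ≈1.20 and ≈1.40).
- `pytest -q tests/` runs the full suite, including one acceptance test
  per release criterion (`tests/test_acceptance.py`).  The
  trained-pipeline tests train reduced-width networks from scratch
  inside the session (see `tests/conftest.py`; the bundle is cached
  under `scratch/model_cache/` for local re-runs).  Everything is
  seeded, so results are reproducible on one machine.

See `docs/methods.md` for the models, algorithms and parameter choices.
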