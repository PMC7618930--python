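# trajseg

Per-point segmentation of single-particle trajectories into **moving**
(directed transport) and **not-moving** (stalled, Brownian or confined)
points, using a sliding-window 1D U-Net.

## The problem

Live-cell imaging of secretory vesicles produces thousands of tracks whose
motion switches regime along the way: a vesicle may sit stalled, diffuse,
and then be carried by a motor in a consistent direction. Classical
motion-type analysis is built on the mean squared displacement (MSD), which
needs tens of points per segment to estimate a diffusion exponent — but a
single-slice imaging protocol of intrinsically 3D motion yields mostly
*short* tracks (5–20 points), which MSD-based methods simply cannot
segment.

`trajseg` takes a different route: it slides a fixed 8-point window along
each track, lets a small 1D convolutional encoder–decoder label *every
point inside the window*, and stitches the overlapping window predictions
back into one probability per point. Because the network labels points
rather than windows, the smallest detectable segment is not limited by the
window length, and a 5-point track is segmentable after padding.

## Method in brief

For a track `T = (x_t, y_t)` each window of `W = 8` consecutive points is

1. **origin-normalised**: `T_norm(x, y) = T(x, y) − (x₀, y₀)`, with
   `(x₀, y₀)` the window's own first position — all windows share an origin
   and only within-window displacement survives;
2. **converted to polar coordinates**: `r = √(x² + y²)`,
   `θ = atan2(y, x)` — the radius expresses displacement magnitude in a
   single channel (a Cartesian representation is also available for
   comparison);
3. passed through a 1D U-Net (2 down-sampling blocks of conv+ReLU+maxpool,
   a bottleneck, 2 up-sampling blocks with learned up-convolution and skip
   concatenation, and a 1×1 conv + sigmoid head) producing
   `P(moving)` for each of the 8 positions.

Windows slide with a step of 25 % of `W`; at stitching time only the
centre 50 % of each window contributes (the first and last windows also
contribute their outer quarters), and overlapping contributions are
averaged. Tracks shorter than `W` are padded by repeating the last point;
the padded tail is a stalled segment, labelled not-moving during training
and discarded after stitching. Training uses Adam (lr 1e-4) with binary
cross-entropy; evaluation reports point accuracy with each track's first
point excluded, since one position alone carries no dynamics.

The network, its backpropagation and the Adam optimiser are a
self-contained numpy implementation (~21k parameters) — training runs in
about a minute on one CPU core.

A built-in simulator generates labelled synthetic datasets emulating this
kind of data: many short tracks mixing directed, Brownian, confined and
stalled regimes through a Markov switching process, plus localisation
noise.

## Worked example

```python
from trajseg import TrajectorySegmenter, separable_preset, simulate_dataset

cfg = separable_preset(n_tracks=250, seed=0)
train_trajs, test_trajs = simulate_dataset(cfg, n_test=50)

model = TrajectorySegmenter(train_trajs, coord_system="polar")
res = model.fit(epochs=200, seed=0)
print(res.summary())
print(res.evaluate(test_trajs).summary())
```

prints

```
Trajectory segmentation fit
==============================================
coordinate system : polar
window            : W=8 step=2 center=50%
network           : depth 2, 16 base channels, 20801 parameters
training samples  : 2071 windows
optimizer         : Adam, lr=0.0001, 200 epochs, batch 32
seed              : 0
loss              : 0.8327 (first epoch) -> 0.0312 (final)

Segmentation evaluation (first point of each track excluded)
  scored points : 1296
  accuracy      : 0.9923
  moving        : precision 0.9921  recall 0.9818
  not_moving    : precision 0.9924  recall 0.9967
  confusion     : tp=377 fp=3 fn=7 tn=909
```

200 training tracks expand to 2071 windows; the held-out 50 tracks are
scored on 1296 points (their first points excluded). On this *separable*
preset — directed speed 1.0 versus diffusive step std 0.25 — the model
recovers 99.2 % of the ground-truth point labels. Accuracy on real
annotated microscopy data is substantially lower (human labels are noisy
and the regimes overlap); the simulator's purpose is to verify the
machinery, not to predict real-data performance.

The same experiment from a shell:

```bash
trajseg simulate --n-tracks 250 --n-test 50 --seed 0 \
    --out-train train.csv --out-test test.csv
trajseg train --data train.csv --coord-system polar --seed 0 --out model.ckpt.npz
trajseg segment --model model.ckpt.npz --data test.csv --out segmented.csv
trajseg evaluate --pred segmented.csv --ref test.csv --report report.json
trajseg compare-coords --train train.csv --test test.csv --seed 0
```

`trajseg run --config run.yaml` chains all stages with one global seed and
writes a checksummed manifest. Input CSVs need columns
`track_id, frame, x, y` (plus `label` for training); other header names can
be remapped with `column_map` in the library API.

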