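# Methods

## Problem setting

A trajectory is an ordered sequence of 2D positions of one tracked
particle over consecutive frames, with an optional per-point binary label:
*moving* (directed, motor-driven transport; encoded 1) or *not-moving*
(stalled, Brownian or confined; encoded 0). The package segments
trajectories point-by-point into these two classes. It is aimed at data
where most tracks are short — a regime where MSD-based classification,
which needs long windows to estimate diffusion exponents, is not
applicable.

## Sliding-window model

**Windowing.** Each trajectory is processed in windows of `W = 8` points
sliding with step `round(0.25·W) = 2`. The final window is snapped to
start at `L − W` so the tail is always covered (the alternative — dropping
the partial stride — would leave trailing points covered only by an
interior window's centre, or not at all). Tracks shorter than `W` are
padded to length 8 by repeating the last observed point. The padding
constant is the last point rather than zeros: a repeated point is a
zero-displacement tail, i.e. exactly a stalled segment, which is also why
padded positions are labelled not-moving during training. Padded positions
are flagged and removed after stitching.

**Per-window normalisation.** Every window is translated so its own first
point is the origin (`out[i] = coords[i] − coords[0]`). Normalisation is
deliberately per-window, not per-trajectory: it makes the features
translation-invariant while preserving displacement magnitudes, and every
window is presented to the network in the same frame regardless of where
it sits in the track.

**Polar features.** The default representation is `(r, θ)` with
`r = √(x²+y²)`, `θ = atan2(y, x) ∈ (−π, π]` and `θ(0,0) ≔ 0`. The radius
collapses displacement into one channel irrespective of direction, which
is the property that makes it attractive for training; the Cartesian
`(x, y)` representation is retained as a configuration option and for the
comparison experiment. θ is used raw (wrapped): no unwrapping is applied
across the window, so a trajectory crossing the negative x-axis produces a
2π jump in the θ channel. This representation artifact is accepted — the
network can learn around it, and no principled unwrapping rule exists for
noisy displacements near the origin. Signed-zero inputs are folded onto
the (−π, π] contract.

**Stitching.** Only the centre 50 % of each window (positions 2–5 for
W = 8) contributes to the final segmentation; the first window also
contributes its leading quarter and the last its trailing quarter, which
guarantees every point at least one contribution (verified exhaustively
against a brute-force enumeration for all lengths 8–200). With step 2 and
centre length 4 interior contributions overlap; overlaps are resolved by
unweighted averaging of *probabilities* (not hard labels) before
thresholding — averaging avoids quantisation at window seams and makes no
assumption about which window is more reliable. The hard label is moving
iff the averaged probability exceeds 0.5; an exact tie maps to not-moving
(conservative for the rarer directed class). The threshold is fixed, never
tuned on validation data.

## Network

A 1D U-Net over window positions: 2 encoder levels (conv k=3 'same' →
ReLU → skip → maxpool stride 2), a bottleneck conv, 2 decoder levels
(learned transposed-conv upsampling ×2 → channel concatenation with the
skip → conv → ReLU), and a 1×1 conv + sigmoid head. Channel widths are
16 → 32 with a 64-channel bottleneck and are a package choice — kept small
to match the 8-point window and CPU training; at `W = 8` the bottleneck
sequence length is 2, so deeper nets have nothing left to pool. The head
is a single sigmoid channel: with two classes, `P(not_moving) = 1 −
P(moving)` and binary cross-entropy is equivalent to a two-channel softmax
with cross-entropy, while halving head parameters. No batch normalisation
or dropout. Skip connections concatenate rather than add (the standard
U-Net choice, letting the decoder weight fine-grained and coarse features
independently).

The layers, backpropagation and Adam are implemented directly on numpy
float64 arrays (`trajseg.nn`): the model has ~21k parameters and 8-point
inputs, so a framework-free implementation is fast enough (a few ms per
batch) and makes seeded runs bit-reproducible on any CPU. The backward
pass is verified against central finite differences in the test suite.

## Training

One sample per enumerated window of every labelled track. Loss: binary
cross-entropy averaged over counted points, with predictions clamped to
`[1e−12, 1−1e−12]` for finiteness. Padded positions are counted in the
loss as not-moving by default (they are genuine stalled segments under the
repeat-last padding); a switch excludes them for ablation. Optimiser:
Adam, learning rate 1e-4 (β₁ = 0.9, β₂ = 0.999). Epochs (200), batch size
(32) and per-epoch shuffling are package choices sized for CPU-minutes
training and exposed in `TrainConfig`. Train/test splitting is always by
trajectory, never by window — overlapping windows of one track share
points, so a window-level split would leak test information into training.

## Synthetic data generator

The simulator stands in for annotated microscopy data and defines the
study conditions for the acceptance tests. It emulates the structural
features of single-slice vesicle tracking: many short tracks (lengths
drawn from a shifted geometric distribution, mean ≈ 25, truncated to
[5, 135] — the strong short-track skew comes from 3D motion leaving a thin
focal plane), mixed motion regimes within single tracks, and localisation
noise.

Per-frame updates, with state switching by a Markov chain whose dwell
times are geometric (mean 10 frames; on exit, the next state is uniform
over the others):

| state    | update                                              | label |
|----------|-----------------------------------------------------|-------|
| directed | `x += v(cos φ, sin φ)`, `φ += N(0, σ_φ²)`           | 1     |
| brownian | `x += N(0, σ_B² I)`                                 | 0     |
| confined | `x += κ(anchor − x) + N(0, σ_C² I)`                 | 0     |
| stalled  | `x` unchanged                                       | 0     |

Headings and anchors are re-drawn on state entry; observed positions add
`N(0, σ_loc² I)`. The label of point *t* is the state that generated the
step into *t* — consistent with the evaluation protocol that a lone first
point has no dynamics.

The **separable** preset (`v = 1.0, σ_φ = 0.2, σ_B = σ_C = 0.25,
κ = 0.5, σ_loc = 0.05`, all in coordinate units per frame) makes directed
steps ~4× longer than diffusive ones, so ground-truth labels are
recoverable and the pipeline's label-recovery bound (accuracy ≥ 0.85 on
held-out tracks) is meaningful. A **hard** preset (`v = 0.4, σ_B = 0.3`)
with overlapping step statistics is provided for stress testing, with no
accuracy guarantee. With the default switching process the stationary
distribution is uniform over the four states, so about 25 % of points are
moving — a realistic class imbalance.

What the simulator does *not* emulate: annotation noise and annotator
boundary conventions (its labels switch exactly at state changes), missed
detections and track fragmentation, blinking, anisotropic or
depth-dependent localisation error, and 3D motion. High accuracy on the
separable preset therefore demonstrates that windowing, features, network,
training and stitching work as specified — not that comparable accuracy
would be reached on manually annotated microscopy data, where reported
accuracies are far lower.

## Evaluation protocol

Point accuracy micro-averaged over all scored points, with index 0 of
every track excluded (`n_scored = Σ(L_i − 1)`). Micro-averaging is the
plain reading of "accuracy of the segmentation"; per-trajectory accuracies
are also reported for inspection, along with per-class precision/recall
and the confusion counts, because accuracy alone can hide a degenerate
classifier under class imbalance. The coordinate-comparison experiment
trains twin models — identical data, seed and hyperparameters, differing
only in Cartesian vs polar features — and reports both accuracies without
asserting an ordering: the margin between the representations is small and
dataset-dependent.

## Numerical and reproducibility choices

* All arithmetic in float64; checkpoints store raw float64 weights, so
  save → load reproduces forward outputs bit-identically.
* One global seed; per-stage seeds are derived as the first 4 bytes of
  `SHA-256("{seed}:{stage}")` mod 2³¹, so each pipeline stage is
  reproducible in isolation.
* CSV coordinates are written with 17 significant digits and parsed with
  round-trip float precision: write → read is exact and seeded datasets
  are byte-identical.
* Max-pool ties resolve to the first position; the loss at a masked-out
  point contributes exactly zero gradient.
* Degenerate inputs: length-1 tracks are padded to a single all-pad
  window; constant tracks normalise to all-zero features; non-finite
  coordinates are rejected at validation.

## Problem sizes

The shipped experiment sizes — 200 training / 50 test tracks (~2000
windows, ~5000 points), 200 epochs, and 10⁴-step single-regime tracks for
the diffusion diagnostics — are chosen so the full protocol, including the
twin-model comparison, completes in a few CPU-minutes while keeping
Monte-Carlo error well inside the stated tolerances (the Brownian MSD
slope check at 10⁴ steps has ~2 % sampling error against its 15 % band).

## Known limitations

* Two classes only; separating stalled from confined within not-moving
  would need a multi-class head and richer training data.
* 2D trajectories only; frame gaps are tolerated on input but treated as
  consecutive points, which distorts features if gaps are long.
* No post-hoc smoothing of the label sequence (no HMM decoding or minimum
  segment length); isolated single-point flips are possible.
* The θ channel's wrap discontinuity can perturb windows whose
  displacement hovers near the negative x-axis.
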