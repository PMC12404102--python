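# Methods

This note records the models, conventions and design choices behind `ripc`,
in the spirit of the methods documentation that accompanies simulation and
analysis packages: what is computed, under which assumptions, and which
decisions were genuinely open.

## Data model

A reconstructed single-cell volume is a voxel set
V = {v_i = (x_i, y_i, z_i, n_i)}, i = 1..N, where n_i is the refractive
index (RI) of voxel i and coordinates are voxel index x spacing (0-based,
micrometres).  Sampling produces a point cloud
P = {p_j = (x_j, y_j, z_j, n_j)}, j = 1..M, with M << N.  Foreground (cell)
voxels number roughly 5x10^5 to 4x10^6 on a 320 x 320 x 210 grid; the
package's desk-scale default is a 160 x 160 x 105 grid at 0.2 um spacing —
the same physical field at 1/8 the voxel count — with the full-scale grid
available behind a flag.

## Synthetic phantoms

No imaging dataset is bundled, so every stage is exercised on synthetic RI
phantoms that reproduce the statistical structure the pipeline relies on:

* geometry: a randomly oriented ellipsoidal cell (semiaxes ~8 x 7 x 5.5 um,
  +-15% per-sample jitter), an interior nucleus ellipsoid at 0.55x the cell
  axes, spherical nucleoli inside the nucleus, and sparse small lipid
  droplets in the outer cytoplasm.  Spheres and ellipsoids only — no claim
  of realistic organelle morphology.
* RI structure: background exactly at the medium (1.330); cytoplasm confined
  to the lower part of its band (1.3355-1.3395 with a mild centre-out
  gradient); nucleolus values drawn per nucleolus from a normal with
  sigma 0.001, clipped to [1.345, 1.355]; droplet values uniform inside
  [1.357, 1.378]; optional Gaussian voxel noise (default sigma 0.0015 RI)
  added everywhere.  The resulting histogram over 6 equal-width intervals is
  skewed by >= 3 orders of magnitude between the lowest and highest
  interval, matching real single-cell RI volumes.
* classes: three viability-like classes differing in nucleolar count
  (2/3/4), radius (1.4/1.3/1.2 um) and mean nucleolar RI
  (1.352/1.350/1.348).  The direction of the RI shift is a configurable
  synthetic convention; the defaults merely guarantee a monotone,
  recoverable contrast.  Note that with these radii the total nucleolar
  volume is nearly equal across classes, so the band *fraction* carries
  little signal and class recovery rests on the band's RI level and spatial
  arrangement — a deliberately non-trivial target.

What the phantoms do not emulate: diffraction and missing-cone artifacts,
reconstruction bias, textured organelles, cell-cycle morphology.  Passing
tests on phantoms therefore validate the pipeline's mechanics and its
relative comparisons (e.g. 4-channel vs 3-channel inputs), not clinical
performance on real tomograms.

## Voxel-to-cloud sampling

`random_sample` draws M points uniformly without replacement.  Because the
RI histogram is dominated by cytoplasm, uniform draws starve the high-RI
organelles; `segmented_equilibrium_sample` instead normalizes the RI range,
splits it into L equal-width intervals (default L=6, M=10,000), draws
floor(M/L) per interval (remainder to the lowest-index intervals), takes
everything from intervals with fewer points than their quota, and fills the
total deficit uniformly from the still-unsampled points of the other
intervals.  Every output point is a genuine input point and the output size
is exactly M.

Open choices, resolved as follows:

* RI normalization before interval division defaults to per-cell min-max;
  a fixed physical range [1.33, 1.40] is available when absolute RI
  comparability across samples matters (and is what the interval-balance
  tests use, since it decouples bin edges from the sample).
* Remainder handling (L does not divide M): quotas of floor(M/L) with the
  remainder assigned to the lowest-index intervals — deterministic and
  order-independent.
* Supplementation draws uniformly from the pooled unsampled points of the
  surplus intervals, not proportionally per interval.
* Sampling is strictly without replacement; requesting M > |P| is an error.

Clouds are normalized to the unit sphere (centroid-centred, divided by the
maximum centroid distance) before entering the selector and network; the RI
channel always keeps raw physical values through this step.

## RIPCS: the hybrid point selector

The network consumes a fixed K-point set S = S_FPS u S_RI (default
K = 1024 = 800 + 224):

* Farthest point sampling greedily adds the point maximizing the minimum
  distance to the selected set.  It is RI-blind.  The start point is a
  seeded uniform draw during training (selection stochasticity doubles as
  augmentation) and deterministic for inference: the point farthest from
  the centroid, ties broken by lexicographic coordinate order.
* RI-interval-enhanced sampling draws from the closed nucleolar band
  [1.345, 1.355].  A band with >= k points yields a uniform draw without
  replacement; an underpopulated band is replicated cyclically in shuffled
  order, so multiplicities differ by at most one.
* The union is a multiset concatenation: a point picked by both samplers
  appears twice, which is what guarantees |S| = K for the fixed-size network
  input.  Per-point provenance (FPS vs RIIES) is preserved through PLY I/O.

When K is scaled below 1024 the band draw is kept at its full-scale value
of 224 and the FPS subset absorbs the reduction (capped so FPS keeps at
least K/8): the band statistics the classifier depends on have standard
error ~ 1/sqrt(n_riies), while FPS coverage degrades only mildly with
fewer points.  At K = 1024 the split is exactly 800/224; the desk-scale
profile at K = 256 is 32 FPS + 224 RIIES.

## Network

Three set-abstraction levels and a three-layer head:

| stage | centres | radius | n_sample | widths |
|---|---|---|---|---|
| SA1 | 512 (FPS) | 0.15 | 32 | 64, 64, 128 |
| SA2 | 256 (FPS) | 0.30 | 64 | 128, 128, 256 |
| SA3 | group all | — | — | 256, 512, 1024 |
| head | 1024 -> 512 -> 256 -> 3 | | | dropout 0.3 / 0.4, log-softmax |

Grouping uses a ball query of unitless radius (inputs are unit-sphere
normalized) capped at n_sample points per region.  Groups are filled
nearest-first and padded by repeating the nearest in-radius index; a centre
is always its own neighbour at distance zero.  Nearest-first ordering (and a
deterministic FPS start inside the SA levels, in train and eval alike) is
what makes the eval-mode forward pass exactly invariant to input point
order; index-ordered group filling would break that invariance whenever a
ball holds more than n_sample points.

Layer-width accounting: level 1 consumes the raw channels (local xyz
replaces global xyz; standardized RI rides as the 4th channel), deeper
levels consume the previous pooled width plus 3 local coordinates (131 and
259).  Every pointwise layer and the two hidden head layers carry batch
normalization with affine scale/shift; the final 3-unit layer does not.
This is the unique placement that yields the 1.47 M parameter total the
closed-form counter and the model enumeration both produce.

The RI channel is standardized as (n - ri_center)/ri_scale with defaults
(1.33, 0.07), mapping the physical intracellular span onto [0, 1].  The
desk-scale (`tiny`) profile uses ri_scale = 0.0035: its phantom classes are
separated by RI contrasts of ~2x10^-3, and with the default scaling that
signal carries ~1e-3 of the input variance entering layer 1 — too little
for the short desk-scale schedule (450 optimizer steps) to amplify.  This
is a feature-scaling choice of the network profile; raw RI is untouched.

Numerics: float32 parameters and activations (float64 available for
gradient checking, which passes at 1e-5 against central differences);
He-style init; batch-norm momentum 0.1 with running statistics at eval;
inverted dropout, train mode only.

### Parameter and FLOP accounting

Parameters: per affine layer in*out + out, plus 2*out for each batch-norm
placement (all but the final layer).  Default 4-channel model: 1,466,243
scalars = 1.47 M; the 3-channel variant differs by exactly 64 first-layer
weights.

FLOPs: one multiply-accumulate in a pointwise/affine layer counts as one
FLOP (the common profiler convention; stated explicitly because FLOP
counters in the wild differ).  Grouped sizes are 512x32, 256x64 and 1x256 for the three
levels plus the head's single vector, giving 1.471x10^9 MACs at a 1024 x 4
input.  Elementwise work (bias, normalization, ReLU, pooling) is excluded
from the headline figure and reported separately in the breakdown
(~5x10^7 ops, i.e. ~3% — the convention choice does not move the order of
magnitude).

## Training protocol

AdamW (lr 1e-3, weight decay 1e-4, betas (0.9, 0.99); beta2 = 0.99 adapts
the second moment quickly enough for short schedules), batch 16, cosine annealing
lr_e = lr (1 + cos(pi e/E))/2 to zero without restarts, label-smoothed
cross-entropy (alpha = 0.1).  Each epoch re-draws every sample's RIPCS
point set (fresh seeds, random FPS start) — selection stochasticity is the
principal augmentation — and then applies, independently with probability
0.5 each: a uniform rotation about z, per-coordinate Gaussian jitter
(sigma 0.01, clipped at +-0.05), and Gaussian RI noise (sigma 0.002).
The magnitudes follow common point-cloud practice and are exposed in the
config.  Evaluation always uses the
deterministic RIPCS variant and eval-mode forward passes.

The 8:2 stratified split allocates floor(0.8 n_c) per class to training
(e.g. (123, 179, 154) -> 364/92).  k-fold cross-validation (default k=5,
a conventional choice) is for tuning only; reported metrics come from the
single fixed split.

Metrics: accuracy, macro recall/precision/F1, one-vs-rest AUC per class
(undefined and excluded from the mean when a class is absent from the test
set, with a warning), and the 3x3 confusion matrix — all via scikit-learn.

## Desk-scale experiment matrix

The eight named arms (3D/4D x random/segmented x FPS/RIIES/hybrid) run on a
shared phantom dataset: 60 cells per class on a 96 x 96 x 63 grid
(1/3 um spacing), M = 2048, K = 256, tiny network profile, 50 epochs —
sizes chosen so the full two-arm comparison over five seeds completes on a
single CPU in minutes.  On these phantoms the 4-channel segmented+hybrid
arm reaches held-out accuracy >= 0.8 and beats the 3-channel FPS-only arm
— the expected direction when the class signal rides on the RI band.
A robustness harness re-evaluates a fitted model under repeated random
RIPCS draws and reports mean +- sd accuracy.

A note on what limits desk-scale accuracy: max pooling (the architecture's
aggregation) natively extracts extreme-value statistics.  On the phantoms,
a 256-point draw's band maximum separates the classes at only ~0.72 while
the band mean reaches ~0.92 (logistic probe); the heavier RIIES share and
the RI channel gain are what let the hierarchy approximate band-level
statistics beyond the raw maximum.

## Known limitations

* Phantoms are geometric idealizations; absolute accuracies on them do not
  transfer to real tomograms.
* The FLOP figure is convention-dependent; comparisons against tools that
  do not state their counting convention are indicative only.
* Training is CPU-oriented and single-threaded numpy; wall-clock scales
  roughly linearly in epochs x samples x network MACs.
* Batch normalization uses running averages at eval; per-batch statistics
  at inference would break the determinism contracts the tests rely on.
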