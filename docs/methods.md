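# Methods

## Problem and model

The package segments five blastocyst components (background, zona
pellucida, trophectoderm, inner cell mass, blastocoele) from square
grayscale images. The segmenter is an encoder–decoder network whose
encoder replaces convolution blocks with axial-free attention blocks:

1. **Grid generator.** For angle θ ∈ [0, π) and output pixel with centred
   coordinate p = (x, y) (x = column, y = row, origin at
   ((W−1)/2, (H−1)/2)), the source coordinate is R_θ·p with
   R_θ = [[cos θ, −sin θ], [sin θ, cos θ]]. The inverse map is the same
   grid evaluated at −θ (exposed as an `inverse` flag because angles are
   restricted to [0, π)). The (x, y) vs (row, col) ordering, which the
   formula alone does not fix, is resolved as x = col, y = row; any
   consistent choice yields an equivalent model.
2. **Direction sampler.** Zero-padded bilinear interpolation with kernel
   max(0, 1−|Δx|)·max(0, 1−|Δy|), applied identically per channel.
   Coordinates outside the input contribute exactly zero; no
   reflection/replication variants, and no bicubic option. Grids are kept
   in unnormalized pixel units.
3. **Bank selection.** Rather than sampling 1D lines individually, the
   full rotated map is materialized and its rows are the attention banks.
   For θ < π/2 the map is rotated by θ and the banks are rows of length W;
   for θ ≥ π/2 it is rotated by θ − π/2 and the banks are columns of
   length H. At θ = 0 and θ = π/2 the grids are identities and the layer
   reduces *exactly* (no resampling blur) to width- and height-axis
   attention — the property the oracle tests pin down. Per-layer cost is
   O(H·W·W) or O(H·W·H).
4. **1D attention.** Logits are qᵀk + qᵀr^Q + kᵀr^K over the bank, values
   are v + r^V, softmax is max-subtracted per bank for numerical
   stability (an implementation choice, not part of the formula). Heads
   are computed independently and concatenated; the default head count is
   2 (a package choice — nothing in the attention formulation fixes it).
5. **LSRPE.** The positional tables are indexed by the *signed* along-bank
   offset b−a ∈ [−(L−1), L−1] (2L−1 entries per role per head). The
   two-factor 2D form of the sinusoidal encoding collapses in a 1D bank to
   a single sine factor per offset because only one offset coordinate
   varies along a bank; the package therefore learns one angle table per
   role. Angles are stored unconstrained and mapped through
   (π/2)·sigmoid(raw), which keeps them in [0, π/2] with live gradients
   at the boundary (a smooth alternative to clamping); initial raw values
   are uniform in [−2, 2] so initial encodings are spread over most of
   [0, 1] and independent across the Q/K/V roles. The LRPE ablation
   baseline is a directly-learnable additive table with no sinusoid and
   no constraint; this is the package's definition of a "plain learnable
   relative positional encoding" baseline.
6. **Output alignment.** Attention output is computed in the rotated frame
   and rotated back by the inverse grid before aggregation. The
   alternative — aggregating in rotated frames — would sum spatially
   misaligned maps, which makes the pixelwise aggregation meaningless, so
   alignment is the default (the rotated-frame variant is deliberately not
   offered).
7. **Soft aggregation.** "sum(Y)" is read as global spatial summation to a
   per-channel descriptor (Split-Attention style): each direction's
   descriptor passes a per-direction one-layer channel mixer, a softmax
   across directions per channel produces the weights, and the weighted
   sum is added to a concatenation branch (channel concat + 1×1 conv).
   Because the descriptors are global, the weights are per-channel rather
   than per-pixel. Ablation variants: `add` (plain sum), `wadd` (one
   learnable scalar per direction), `cat` (concat branch only), `agg`
   (weighted branch only), `soft` (both).
8. **Block structure.** The two 1×1 convolutions sit on the transform
   path (channel shuffle before the parallel attention layers and after
   aggregation); the skip is the identity, with a 1×1 projection only on
   channel change — standard residual practice; placing both 1×1
   convolutions on the skip instead would be the other defensible
   reading of a residual "shuffle", and was not taken. Max pooling is applied once per
   block, after the residual sum. Each of the D directions has independent
   projections and positional tables.
9. **Network.** Stem: two Conv-BN-ReLU pairs, the first pooled 2×2, the
   second not; then the attention stages (each halving resolution); a
   U-Net-style decoder (bilinear ×2 upsampling by default, a
   nearest+conv variant behind `upsample="tconv"`, concat skip fusion,
   Conv-BN-ReLU); 1×1 head to 5 classes. Deep supervision adds a 1×1
   head at every intermediate decoder scale; auxiliary losses use
   nearest-downsampled masks with weight 0.4 each (a package default).
   Stage widths/counts are configuration, not facts: the default is
   3 stages (64, 128, 256) at input 256 with stem width 32;
   `NetworkConfig.tiny()` is 2 stages (32, 64), stem 16, input 64,
   ≈0.21 M parameters — the desk-scale study condition used by the tests
   and the acceptance script.

## Loss and metrics

The per-class soft Jaccard uses softmax probabilities during training and
the formula's ε = 1e−3; evaluation metrics use hard argmax labels. The
weighted loss adds w1 = 1.0 on the worst class and w2 = 0.8 on the second
worst (selected by a stable sort; gradients flow only to the selected
components, and the loss is continuous through ties). Its optimum over
valid 5-class SJA vectors is −(5 + 1.0 + 0.8) = −6.8; with deep
supervision the *logged* training loss additionally includes the weighted
auxiliary terms, so its own bound is −6.8·(1 + 0.4·n_aux). Metrics are
one-vs-rest accuracy/precision/recall/Dice/Jaccard in percent,
macro-averaged over all 5 classes by default; per-class and
foreground-only (4-class) reductions are exposed because the single-number
reduction convention is not otherwise fixed. A class with a zero
denominator is reported undefined, excluded from the macro mean and
logged.

## Training recipe

Defaults: Adam with β1 = 0.9 (the recipe's "momentum" is read as Adam's
first-moment decay, since Adam has no classical momentum knob),
β2 = 0.999, base LR 8e−4, weight decay 5e−4 added to the gradient
(coupled L2), Poly LR schedule with power 0.9 (the DeepLab-line
convention), 2000 epochs as the
configured default, batch size 8, seeded 80/20 train/val split when no
validation set is given. Augmentation applies one affine map per sample —
scale U(0.8, 1.2), rotation U(0, 2π) (full circle, justified by rotation
consistency), random crop offset, horizontal flip p = 0.5 — bilinear for
images, nearest for masks. Non-finite loss aborts with the epoch,
iteration, LR and batch indices.

## Automatic differentiation

No GPU/tensor framework is used: `btformer.autodiff` is a tape-based
reverse-mode engine over numpy arrays (elementwise ops, reductions,
two-operand einsum, softmax, stride-1 conv2d via sliding windows, 2×2 max
pool, gather/scatter primitives for bilinear sampling and positional-table
lookup). Every operator's gradient is verified against central finite
differences in the unit tests. Training is bit-deterministic for a fixed
seed; the double-precision determinism test constructs the model with
`dtype="float64"`, while training defaults to float32 for speed.

## Synthetic phantoms

`btformer.phantom` generates the study data: a ZP annulus enclosing a TE
rim enclosing the blastocoele lumen, with the ICM as an ellipse tangent to
the lumen boundary (radial major axis), centre jitter ±3 %, embryo radius
U(0.33, 0.42)·size, ZP thickness U(0.06, 0.10)·size, TE thickness
U(0.05, 0.09)·size, ICM radial semi-axis U(0.38, 0.55) of the lumen
radius, axis ratio 1−U(0, 0.4). Images are per-class base intensities
plus a directional illumination ramp (a stand-in for the Hoffman relief
gradient), Gaussian blur and additive Gaussian noise; the Gaussian
intensity/noise family is the package's choice — the real data are only
characterized qualitatively (poor contrast, noise, ambiguous boundaries).
Three difficulty presets control contrast: at `hard` the TE/blastocoele
intensity step falls below the noise σ, reproducing the local-ambiguity
regime. `medium` is the default study condition. Every generated mask
contains all five classes (redrawn otherwise) and regenerates
bit-identically from its JSON manifest.

What the phantoms do **not** emulate: real optics (speckle, defocus,
three-dimensional relief), irregular tissue boundaries, fragmented ICM,
expansion-stage variation, and annotation noise. Passing the scaled-down
learning tests therefore shows that the architecture, losses and training
loop work end-to-end and can exploit the concentric/rotational structure;
it does not certify clinical-grade accuracy on real blastocyst images.

## Problem sizes and numerical choices

The tests and the acceptance script use the tiny configuration: 200
training / 50 held-out phantoms at 64×64, 30 epochs, batch 8 — sizes
chosen so a full run completes in minutes on one CPU while still giving a
meaningful held-out signal. The single-sample memorization check runs 200
Adam steps at LR 3e−3 without weight decay (a standard overfit sanity
setting; the model is unchanged). The ERF probe backpropagates a unit
signal from one output pixel and thresholds |grad| at 1 % of its maximum —
the package's concrete definition of "non-negligible"; ERF counts are
compared between D = 1 and D = 4 on a fixed seed. The ablation harness
runs all five axes (D 1–5; PE none/LRPE/LSRPE; aggregation
add/wadd/cat/agg/soft; supervision on/off; loss CE/SJA/WSJA) at reduced
sizes purely to verify wiring and report format; its Dice numbers at those
sizes are not meaningful comparisons.

## Known limitations

* CPU-only and numpy-based: roughly two orders of magnitude slower than a
  GPU framework; the default 256-input configuration is provided and
  shape-tested but full-scale 2000-epoch training is out of reach here.
* The real 249-image public blastocyst dataset is not bundled; a folder
  loader (`PhantomDataset.load`-compatible layout) covers externally
  prepared data, but all quantitative claims in this repository are about
  phantoms.
* Batch normalisation statistics make per-sample predictions depend on
  training-batch composition during training mode; evaluation always uses
  running statistics.
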