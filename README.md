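# btformer

Segmentation of human blastocyst components — background, zona pellucida
(ZP), trophectoderm (TE), inner cell mass (ICM) and blastocoele — from
microscopy-style images, using an encoder–decoder network whose encoder is
built from **axial-free attention blocks**, plus a synthetic
blastocyst-phantom generator so the whole pipeline trains and validates at
desk scale on a single CPU.

## Why

Grading an embryo before IVF transfer depends on the morphology of its
tissue compartments, so their automatic segmentation matters clinically.
Blastocyst images are hard for local models: distinct tissues share local
texture (*local inconsistency*), so context is required, and the images
keep their semantics under any rotation about the embryo centre
(*rotation consistency*). The architecture here exploits both.

## The model

Dense 2D self-attention on an H×W map costs O(H²W²). Axial attention
restricts each pixel's attention to its row or column, cutting the cost to
O(HW²) / O(H²W). **Axial-free attention** generalizes the axis to any angle
θ ∈ [0, π): a rotation grid

    (x, y)ᵀ = R_θ (x′, y′)ᵀ,   R_θ = [[cos θ, −sin θ], [sin θ, cos θ]]

maps the feature map into a rotated frame via a zero-padded bilinear
sampler, 1D multi-head attention runs along the rows (θ < π/2) or columns
(θ ≥ π/2) of the rotated map, and the result is rotated back. The attention
logits carry a learnable sinusoidal relative positional encoding (LSRPE):
for signed along-bank offset b−a, each of the Q/K/V roles owns learnable
angles in [0, π/2] whose sine is added as

    softmax_b( qᵀk + qᵀr^Q_{b−a} + kᵀr^K_{b−a} ) · (v_b + r^V_{b−a}).

An **axial-free attention block** runs D such layers in parallel at the
uniformly spaced angles d·π/D (D·θ̄ = π) and fuses them by *soft
aggregation*: a softmax over directions (weighted per channel from global
descriptors) plus a concatenation branch with a 1×1 convolution, inside a
residual, followed by 2×2 max pooling. Training minimizes the **weighted
soft-Jaccard loss**

    SJA_i = (Σ y_i ŷ_i + ε) / (Σ y_i + Σ ŷ_i − Σ y_i ŷ_i + ε),  ε = 1e−3
    L = −sum(SJA) − 1.0·min(SJA) − 0.8·second_min(SJA)

whose optimum over the five classes is −6.8, with optional
deep-supervision auxiliary losses at the intermediate decoder scales.

Everything — including reverse-mode automatic differentiation — is
implemented on numpy in this package; see `docs/methods.md`.

## Worked example

```python
from btformer import BlastocystSegmenter, NetworkConfig, TrainConfig

seg = BlastocystSegmenter.from_phantoms(
    n_train=200, n_val=50, size=64, seed=0,
    network=NetworkConfig.tiny(seed=0),
    training=TrainConfig(epochs=30, seed=0, val_every=5))
fit = seg.fit().use_best()
print(fit.summary())
```

prints (30 CPU-epochs on 200 synthetic 64×64 phantoms):

```
Blastocyst segmentation fit
============================================================
network: 2 attention stages (32, 64), D=4, heads=2, pe=lsrpe, agg=soft
parameters: 206,431   forward MACs @64px: 98,316,288
loss: wsja   epochs: 30   base_lr: 0.0008
final training loss: -10.3994
best val macro Dice: 96.29% (epoch 29)
------------------------------------------------------------
per-class validation Dice (%) at last scored epoch:
  background    99.49
  ZP            96.20
  TE            93.13
  ICM           96.26
  blastocoele   96.35
============================================================
```

The training loss is below the plain WSJA optimum of −6.8 because the
logged value includes the two deep-supervision auxiliary terms (bound
−6.8 × 1.8 = −12.24). On the 50 held-out phantoms this fit reaches macro
Dice 96.29% and Jaccard 92.91%.

`fit.evaluate(pairs)` returns percent accuracy / precision / recall /
Dice / Jaccard (macro over the five one-vs-rest classes by default;
per-class and foreground-only reductions are available), `fit.predict`
writes indexed-mask PNGs and colour overlays, and `fit.plot_erf` shows the
effective receptive field of any output pixel.

The same workflows are available from the shell:

```bash
btformer generate --n 200 --size 64 --seed 0 --out data/
btformer train --data data/ --out run/ --epochs 30
btformer evaluate --ckpt run/checkpoint.npz --data data/
btformer predict --ckpt run/checkpoint.npz --images data/images --out preds/
btformer erf --ckpt run/checkpoint.npz --image data/images/phantom_0000.png --out erf.png
btformer ablate --axis D --epochs 5
```

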