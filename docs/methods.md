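# Methods

## Problem and scope

Staging bladder cancer hinges on whether the tumor infiltrates the muscular
bladder wall, which makes joint segmentation of the wall and the tumor on
T2-weighted MRI clinically important — and hard, because the two tissues
have overlapping intensity distributions and blurred boundaries, and
high-quality annotations are scarce. This package implements a
segmentation framework built for exactly that regime: self-supervised
pre-training on unannotated images, semi-supervised fine-tuning that uses
labeled and unlabeled images together, and anatomically informed inference
post-processing. The clinical MRI cohort the method was developed on is not
publicly available, so the package ships a synthetic phantom generator that
reproduces the statistical structure of the task, and every claim the test
suite makes is about behavior on those phantoms.

## Synthetic phantoms

Each phantom is one bladder in a 2D grayscale image: a random ellipse of
bright "urine" (mean intensity 0.85), surrounded by a closed dark "wall"
ring of Euclidean thickness 3–6 px (mean 0.25), on a 0.10 background. With
probability 0.9 a star-convex "tumor" blob (radius 5–10 px, harmonically
perturbed) is grown from a random wall pixel, replacing the wall/lumen
pixels it covers; its mean intensity 0.45 sits between wall and urine so
that, after Gaussian boundary blur (sigma 1 px) and additive Gaussian noise
(sigma 0.03, clipped to [0,1]), the wall/tumor boundary is genuinely
ambiguous — the difficulty the method exists to handle. The foreground
union {urine, wall, tumor} is a single hole-free 8-connected component by
construction, which is the anatomical prior the post-processing stage
enforces on predictions.

Defaults: 96x96 images (the clinical pipeline crops 256x256 from 512x512
slices; the package's problem sizes are scaled to a single CPU), one
bladder per image, label classes {0: background, 1: urine, 2: wall,
3: tumor}. What the phantoms deliberately do not model: MRI physics (bias
fields, Rician noise), 3D slice correlation, multi-focal lesions, catheter
or artifact cases, and anatomical context outside the bladder. Passing
tests therefore demonstrate that the pipeline's machinery is correct and
that its inductive biases work when the modeled structure is present; they
say nothing about accuracy on clinical MRI.

## Stage 1 — wall-enhanced self-supervised pre-training

Random square patches are cropped from unannotated images (default 64 px
at desk scale). From each patch two masked views are built independently:
5–10 axis-aligned square holes with side 15–20 px, filled with i.i.d.
uniform noise on [0,1] (hole counts/sides and the noise law are
configurable; holes may overlap and simply overwrite). Both views pass
through the reconstruction network and the loss

    L_self = L_con + L_rec,
    L_con = mean |r1 - r2|,
    L_rec = mean |r1 - x| + mean |r2 - x|

ties the twin reconstructions to each other and to the unmasked original.
Pixel sums are implemented as means so the loss scale (and hence usable
learning rates) does not depend on patch size; a `reduction: "sum"` switch
restores literal sums. Optimizer: Adam; best model by validation loss on a
held-out 20% of the image pool with frozen validation pairs.

## Networks

Both stages share a symmetric encoder-decoder trunk with index-preserving
unpooling. The encoder is nine conv blocks arranged 3-3-3 between three 2x2
max-pooling stages; each pooling stage records the per-window argmax (ties:
first element in row-major order) so the decoder's unpooling stages can put
values back at the exact positions they came from (zeros elsewhere). The
decoder interleaves four conv blocks 1-1-2 with the three unpooling stages.
A conv block is conv(3x3, same padding) -> batch normalization -> leaky
ReLU (slope 0.01). Channel widths grow (w, 2w, 4w) along the encoder; w
defaults to 16, and the test suite runs at w = 8 (desk scale). The
reconstruction head is a 1x1 conv + sigmoid; the segmentation head is a 1x1
conv + per-pixel softmax over 4 classes.

The exact block interleaving and widths are not architecturally forced;
the chosen arrangement preserves the stated block/pool counts and spatial
symmetry, and the weight-transfer report names every parameter tensor so
the layout is auditable. The trunk parameter sets of the two networks are
identical by construction; `transfer_weights` copies them bitwise
(including batch-norm running statistics) and leaves the segmentation head
and VAE branch at their random initialization.

The VAE branch attaches at the encoder bottleneck: global average pooling,
an affine map to (mu, log sigma^2) (latent dim 16 by default), a
reparameterized sample, an affine map tiled back over the bottleneck grid,
two conv blocks, and a 1x1 conv that reconstructs the bottleneck feature
field. The reconstruction target is the bottleneck itself, treated as
constant (stop-gradient): gradient reaches the encoder only through the
pooled branch input, which keeps the branch a regularizer rather than a
shortcut. An image-target variant was considered (the evidence term is
conventionally written on the input) but the feature-target reading matches
the design of reconstructing "the last layer of the encoder" and is the
default.

## Stage 2 — semi-supervised segmentation

The loss is L_semi = DFL + VAL. DFL (labeled samples only) is a
class-weighted focal cross-entropy

    FL = mean over pixels of -alpha_c (1 - p_c)^gamma log p_c,
    alpha = (0.1 background, 0.1 urine, 0.6 wall, 0.8 tumor), gamma = 2,

plus a soft Dice loss averaged over the foreground classes present in the
ground truth,

    DL_c = 1 - (2 |x∩y| + e) / (|x| + |y| + e),  e = 1e-5,

with probability-weighted intersection. gamma and the background alpha are
free parameters (gamma = 2 is the standard focal default; background is
weighted like urine since both are easy majority classes). Probabilities
inside the log are clamped at 1e-7 so a confidently wrong pixel yields a
large finite loss rather than NaN. VAL = MSE + KL(N(mu, sigma^2) || N(0,1))
is computed on every sample, labeled or not — this is the channel through
which unlabeled images shape the representation.

Each optimizer step draws half its batch from the labeled pool and half
from the unlabeled pool (keeping both loss terms populated every step);
with no unlabeled data the batch is fully labeled and training degenerates
to supervised + VAE. Optimizer: AdamW. Transferred trunk parameters train
at LR1; the randomly initialized head and VAE branch train at
LR2 = beta(n) * LR1, where n is the number of annotated samples and beta
follows the tabulated policy (0.02, 0.2, 2, 10, 20) at n = (42, 21, 12, 4,
1): log-linear interpolation in (log n, log beta) between table points
(the ratio spans three orders of magnitude, so log-log is the natural
monotone fit), clamped to the nearest endpoint outside [1, 42]. Model
selection: mean foreground DSC on a held-out 20% of the labeled set.

The configuration shipped with the test suite uses LR1 = 2e-3 with batch
size 4 at phantom scale. The reference configuration (LR1 = 1e-4, batch 16,
100 epochs — the `PipelineConfig` defaults) is sized for GPU-scale training
on hundreds of clinical slices; with only tens of optimizer steps per epoch
on phantoms, that rate leaves the network visibly under-fitted within the
epoch budget, so the desk-scale runs raise the rate and shrink the batch
(more optimizer steps for the same compute). All are plain config values.

## Stage 3 — inference

Test-time augmentation uses only transforms that are exactly invertible on
the pixel grid — horizontal/vertical flips and quarter-turn rotations — so
inverse(forward(x)) == x bitwise and merging introduces no resampling
error; each candidate transform is verified at registration. The merged
output is the per-pixel mean of the inverse-transformed probability maps
(majority vote available), then argmax (ties toward the lower class index).

Segmentation correction enforces the single-bladder prior: keep the
largest 8-connected component of the foreground union (ties: first in
row-major scan order), then fill interior background holes (4-connected
hole detection — the standard dual of 8-connected foreground). Each filled
pixel takes the majority class of its 8-neighborhood, assigned ring by ring
from the hole boundary inward, because holes arise inside urine or tumor
and should inherit the surrounding tissue; foreground pixels never change
class. Component filtering runs before hole filling. The composite is
idempotent and its output has exactly one hole-free foreground component
whenever any foreground survives.

## Evaluation

Per class: DSC = 2|S∩G|/(|S|+|G|), sensitivity TP/(TP+FN), specificity
TN/(TN+FP), and the full symmetric Hausdorff distance between boundary
point sets (morphological erosion difference), in pixel units with an
optional spacing multiplier for mm. Conventions at edges the formulas leave
undefined: DSC is 1 when both masks are empty; SEN/SPE return 1 on an empty
denominator; HD raises on an empty mask, and a case whose ground truth
lacks a class is excluded from that class's averages (correct absence is
not penalized or rewarded).

## Numerical and implementation notes

The networks are implemented directly on NumPy (float32, NCHW) with manual
backpropagation: im2col + BLAS matmul convolutions, standard batch-norm
backward, pooling-index bookkeeping shared between the pool and unpool
layers, and Adam/AdamW with per-group learning rates. Gradient correctness
is pinned by finite-difference tests on the loss helpers and by brute-force
window enumeration for pool/unpool. Training is deterministic given the
config seed up to floating-point reduction order. BLAS threads are capped
to the usable CPU count at import to avoid oversubscription.

## Known limitations

Phantom realism as above; 2D slices only; a single bladder per image is
assumed by both the generator and the correction stage; the beta policy is
defined by five printed points and its behavior between and beyond them is
an interpolation choice; VAE posterior sampling is replaced by the
posterior mean at inference, so reported probabilities understate latent
uncertainty.
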