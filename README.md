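# bladderseg

Semi-supervised multi-region segmentation of the bladder wall and tumor in
2D grayscale images, with wall-enhanced self-supervised pre-training —
exercised end-to-end on synthetic bladder phantoms.

## The problem

Deciding whether a bladder tumor has invaded the muscle layer (NMIBC vs
MIBC) requires delineating both the bladder wall and the tumor on
T2-weighted MRI, where the two tissues show similar intensities and blurred
boundaries, and expert annotations are scarce. This package implements a
framework built for that low-annotation regime and, because clinical
bladder MRI cannot be redistributed, ships a phantom generator that
reproduces the task's structure: one bladder per image — a bright lumen
(urine), a thin dark wall ring, and usually a wall-attached tumor whose
intensity lies between the two — under boundary blur and noise. Classes:
`{0: background, 1: urine, 2: wall, 3: tumor}`.

## The method

Three stages:

1. **Self-supervised pre-training.** Random patches are cropped from
   unannotated images; two masked views of each patch are made by filling
   5–10 random square holes (side 15–20 px) with noise. A SegNet-style
   encoder-decoder (nine conv blocks / three max-poolings that record
   argmax indices; four conv blocks / three index-preserving unpoolings;
   conv→BN→leaky-ReLU blocks) reconstructs both views under

       L_self = L_con + L_rec
       L_con  = mean |x̂¹ - x̂²|              (contrast consistency)
       L_rec  = mean |x̂¹ - x| + mean |x̂² - x|  (reconstruction observation)

2. **Semi-supervised segmentation.** The pre-trained trunk is transferred
   into a segmentation network (softmax head over 4 classes plus a VAE
   branch at the bottleneck) and fine-tuned with

       L_semi = DFL + VAL
       DFL = FL + DL,  FL = -α_t (1-P_t)^γ log P_t,
                       DL_c = 1 - (2|x∩y|+e)/(|x|+|y|+e)
       VAL = MSE(X, X̂) + KL(N(μ₁,σ₁²) ‖ N(0,1))

   with α = (0.1 urine, 0.6 wall, 0.8 tumor), γ = 2. DFL sees labeled
   samples only; VAL sees labeled and unlabeled samples alike, which is how
   unlabeled images contribute. Transferred layers train at LR1 and
   randomly initialized layers at LR2 = β·LR1, where β = f(n) depends on
   the annotated-sample count n: β = (0.02, 0.2, 2, 10, 20) at
   n = (42, 21, 12, 4, 1), log-log interpolated between and clamped beyond.

3. **Inference.** Test-time augmentation over exactly invertible transforms
   (flips, quarter-turn rotations) with probability-map averaging, then
   anatomical correction: keep the largest connected foreground component
   and fill interior holes — the output is one hole-free bladder region.

Evaluation reports per-class DSC = 2|S∩G|/(|S|+|G|), sensitivity,
specificity, and Hausdorff distance (pixels).

The networks run on a compact NumPy layer library with manual
backpropagation (im2col convolutions, batch norm, pooling-index
bookkeeping, Adam/AdamW) — no GPU or deep-learning framework required.

## Worked example

Generate a phantom cohort (60 labeled / 40 unlabeled / 20 test), pre-train,
fine-tune, predict with TTA + correction, and evaluate:

```sh
bladderseg make-data --config configs/phantom-desk.yaml --out data
bladderseg pretrain  --config configs/phantom-desk.yaml --data data --out pre.npz
bladderseg train     --config configs/phantom-desk.yaml --data data \
                     --ckpt pre.npz --out model.npz
bladderseg predict   --model model.npz --data data --out preds
bladderseg evaluate  --pred preds --data data --out metrics.csv
```

Output of the run above (fixed seeds from the config):

```
wrote 60 labeled / 40 unlabeled / 20 test phantoms to data
pre-trained checkpoint written to pre.npz (best val loss 0.2587)
model written to model.npz (best val DSC 0.9272, n_labeled=60)
wrote 20 predictions to preds
     urine: DSC=0.9947 SPE=0.9995 SEN=0.9924 HD=1.22
      wall: DSC=0.9506 SPE=0.9968 SEN=0.9618 HD=2.19
     tumor: DSC=0.9251 SPE=0.9983 SEN=0.9513 HD=1.89
```

Reading the numbers: the lumen is easy (bright, large); the thin wall ring
and the wall-attached tumor are the hard classes the method targets — DSC
around 0.95 and 0.93 here means the predicted regions overlap the ground
truth by that fraction of their combined area, and the Hausdorff distances
say the worst boundary error is about two pixels. Training history
(per-epoch losses and validation DSC) lands next to each checkpoint as CSV;
`preds/correction_reports.json` records what the anatomical correction
changed per case.

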