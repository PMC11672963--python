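"""Training objectives for both stages.

Self-supervised stage: L_self = L_con + L_rec, where L_con is the L1
discrepancy between the reconstructions of two differently masked views of
the same patch and L_rec penalizes each reconstruction against the unmasked
original.

Segmentation stage: L_semi = DFL + VAL.  DFL is the Dice focal loss — a
class-weighted focal cross-entropy, FL = -alpha_c (1 - p_c)^gamma log p_c,
plus a soft Dice overlap loss DL = 1 - (2|x∩y| + e)/(|x| + |y| + e) averaged
over foreground classes — computed on labeled samples only.  VAL is the VAE
evidence term, MSE(target, reconstruction) + KL(N(mu, sigma^2) || N(0,1)),
computed on labeled and unlabeled samples alike, which is what makes the
training semi-supervised.

Pixel reductions default to means so the loss scale is independent of patch
size; ``reduction="sum"`` restores literal per-pixel sums.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .networks import LatentParams

__all__ = [
    "LossWeights", "contrast_consistency_loss", "reconstruction_observation_loss",
    "self_supervised_loss", "focal_loss", "dice_loss", "dice_focal_loss",
    "kl_standard_normal", "vae_loss", "semi_loss",
]

_CLAMP = 1e-7


@dataclass
class LossWeights:
    """Per-class focal weights and Dice smoothing.

    alpha for urine/wall/tumor follow the published weighting of the easy
    (urine) versus hard (wall, tumor) classes; background defaults to the
    urine weight since both are easy majority classes.  gamma is the focal
    exponent and epsilon the Dice smoothing term.
    """

    alpha_background: float = 0.1
    alpha_urine: float = 0.1
    alpha_wall: float = 0.6
    alpha_tumor: float = 0.8
    gamma: float = 2.0
    epsilon: float = 1e-5
    reduction: str = "mean"
    foreground_classes: tuple[int, ...] = (1, 2, 3)

    def __post_init__(self):
        alphas = self.alpha
        if not np.all((alphas > 0) & (alphas <= 1)):
            raise ValueError("all focal alphas must lie in (0, 1]")
        if self.gamma < 0 or self.epsilon <= 0:
            raise ValueError("gamma must be >= 0 and epsilon > 0")
        if self.reduction not in ("mean", "sum"):
            raise ValueError("reduction must be 'mean' or 'sum'")

    @property
    def alpha(self) -> np.ndarray:
        return np.array([self.alpha_background, self.alpha_urine,
                         self.alpha_wall, self.alpha_tumor], dtype=np.float64)


def _reduce(arr: np.ndarray, reduction: str) -> float:
    return float(arr.mean()) if reduction == "mean" else float(arr.sum())


def _check_same_shape(a, b, what: str):
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"{what}: shape mismatch {a.shape} vs {b.shape}")
    return a, b


def contrast_consistency_loss(r1: np.ndarray, r2: np.ndarray,
                              reduction: str = "mean") -> float:
    """L1 discrepancy between the two reconstructions of twin masked views."""
    r1, r2 = _check_same_shape(r1, r2, "contrast consistency loss")
    return _reduce(np.abs(r1.astype(np.float64) - r2), reduction)


def reconstruction_observation_loss(r1: np.ndarray, r2: np.ndarray, x: np.ndarray,
                                    reduction: str = "mean") -> float:
    """L1(r1, x) + L1(r2, x): both reconstructions against the unmasked original."""
    r1, x = _check_same_shape(r1, x, "reconstruction observation loss")
    r2, x = _check_same_shape(r2, x, "reconstruction observation loss")
    return (_reduce(np.abs(r1.astype(np.float64) - x), reduction)
            + _reduce(np.abs(r2.astype(np.float64) - x), reduction))


def self_supervised_loss(pair, r1: np.ndarray, r2: np.ndarray,
                         reduction: str = "mean") -> float:
    """Total pre-training loss: contrast consistency + reconstruction observation."""
    return (contrast_consistency_loss(r1, r2, reduction)
            + reconstruction_observation_loss(r1, r2, pair.original, reduction))


def _prep_prob_label(prob: np.ndarray, label: np.ndarray):
    prob = np.asarray(prob, dtype=np.float64)
    label = np.asarray(label)
    if prob.ndim != 3:
        raise ValueError("ProbMap must be (num_classes, H, W)")
    if prob.shape[1:] != label.shape:
        raise ValueError(f"probability map {prob.shape} does not match label {label.shape}")
    if label.min() < 0 or label.max() >= prob.shape[0]:
        raise ValueError("label values outside the class range")
    return prob, label.astype(np.int64)


def focal_loss(prob: np.ndarray, label: np.ndarray, w: LossWeights) -> float:
    """Class-weighted focal cross-entropy, reduced over pixels.

    Probabilities at the true class are clamped below at 1e-7 so a confident
    wrong prediction yields a large finite loss, never NaN.
    """
    prob, label = _prep_prob_label(prob, label)
    pt = np.take_along_axis(prob, label[None], axis=0)[0]
    pt = np.clip(pt, _CLAMP, 1.0)
    at = w.alpha[label]
    terms = -at * (1.0 - pt) ** w.gamma * np.log(pt)
    return _reduce(terms, w.reduction)


def dice_loss(pred: np.ndarray, label: np.ndarray, epsilon: float = 1e-5,
              classes: tuple[int, ...] = (1, 2, 3), num_classes: int = 4) -> float:
    """Soft Dice loss, averaged over the foreground classes present.

    DL_c = 1 - (2|x∩y| + e) / (|x| + |y| + e) with probability-weighted
    intersection, so it is 0 when prediction and label agree exactly and
    approaches 1 for disjoint sets as e -> 0.  ``pred`` may be a ProbMap
    (C,H,W) or a hard LabelMap (H,W).
    """
    pred = np.asarray(pred)
    if pred.ndim == 2:  # hard label map -> one-hot
        pred = (pred[None] == np.arange(num_classes)[:, None, None]).astype(np.float64)
    prob, label = _prep_prob_label(pred, label)
    onehot = (label[None] == np.arange(prob.shape[0])[:, None, None])
    losses = []
    for c in classes:
        if not onehot[c].any():
            # class absent from the ground truth: skipped, not averaged in
            continue
        inter = float((prob[c] * onehot[c]).sum())
        size = float(prob[c].sum() + onehot[c].sum())
        losses.append(1.0 - (2.0 * inter + epsilon) / (size + epsilon))
    if not losses:
        return 0.0
    return float(np.mean(losses))


def dice_focal_loss(prob: np.ndarray, label: np.ndarray, w: LossWeights) -> float:
    """DFL = focal loss + Dice loss (exact sum of the two components)."""
    return (focal_loss(prob, label, w)
            + dice_loss(prob, label, w.epsilon, w.foreground_classes))


def kl_standard_normal(lat: LatentParams) -> float:
    """KL(N(mu, sigma^2) || N(0, 1)) for a diagonal Gaussian, summed over
    latent dimensions and averaged over the batch."""
    mu = np.atleast_2d(np.asarray(lat.mu, dtype=np.float64))
    lv = np.atleast_2d(np.asarray(lat.log_var, dtype=np.float64))
    kl = 0.5 * (mu ** 2 + np.exp(lv) - lv - 1.0).sum(axis=1)
    return float(kl.mean())


def vae_loss(target: np.ndarray, reconstruction: np.ndarray, lat: LatentParams) -> float:
    """VAL = MSE(target, reconstruction) + KL(N(mu, sigma^2) || N(0,1))."""
    target, reconstruction = _check_same_shape(target, reconstruction, "VAE loss")
    mse = float(((target.astype(np.float64) - reconstruction) ** 2).mean())
    return mse + kl_standard_normal(lat)


def semi_loss(batch, outputs: dict, w: LossWeights) -> float:
    """L_semi = DFL (labeled samples only) + VAL (all samples).

    ``batch`` is a sequence of (image, label-or-None); ``outputs`` holds the
    stacked network outputs for the same samples: "probs" (N,C,H,W),
    "latent" (LatentParams over the batch), "vae_recon" and "vae_target".
    A fully unlabeled batch contributes only the VAE term.
    """
    if len(batch) == 0:
        raise ValueError("empty batch")
    probs = outputs["probs"]
    dfl_terms = [dice_focal_loss(probs[i], lab, w)
                 for i, (_, lab) in enumerate(batch) if lab is not None]
    dfl = float(np.mean(dfl_terms)) if dfl_terms else 0.0
    val = vae_loss(outputs["vae_target"], outputs["vae_recon"], outputs["latent"])
    return dfl + val


# ---------------------------------------------------------------------------
# gradient helpers used by the training loops (batched, float32)
# ---------------------------------------------------------------------------

def l1_grad(a: np.ndarray, b: np.ndarray, scale: float) -> np.ndarray:
    """d/da of scale * sum|a - b| (mean reduction folds 1/N into scale)."""
    return (scale * np.sign(a - b)).astype(np.float32)


def dice_focal_grad(probs: np.ndarray, labels: np.ndarray, w: LossWeights,
                    labeled_mask: np.ndarray):
    """Batched Dice focal loss and its gradient w.r.t. the probability map.

    probs: (N,C,H,W); labels: (N,H,W) with arbitrary values at unlabeled
    rows; labeled_mask: (N,) bool.  The loss is averaged over labeled
    samples; gradients are zero at unlabeled rows.
    """
    n, c, h, w_ = probs.shape
    grad = np.zeros_like(probs, dtype=np.float64)
    idx = np.flatnonzero(labeled_mask)
    if idx.size == 0:
        return 0.0, grad.astype(np.float32)
    total = 0.0
    alphas = w.alpha
    for i in idx:
        p = probs[i].astype(np.float64)
        lab = labels[i].astype(np.int64)
        onehot = (lab[None] == np.arange(c)[:, None, None])
        # focal term
        pt = np.clip(np.take_along_axis(p, lab[None], axis=0)[0], _CLAMP, 1.0)
        at = alphas[lab]
        npix = h * w_
        total += float((-at * (1.0 - pt) ** w.gamma * np.log(pt)).mean())
        unclamped = np.take_along_axis(p, lab[None], axis=0)[0] >= _CLAMP
        gpt = np.where(
            unclamped,
            -at * ((1.0 - pt) ** w.gamma / np.maximum(pt, _CLAMP)
                   - w.gamma * (1.0 - pt) ** np.maximum(w.gamma - 1.0, 0.0) * np.log(pt)),
            0.0) / npix
        gfocal = np.zeros_like(p)
        np.put_along_axis(gfocal, lab[None], gpt[None], axis=0)
        # soft Dice term over foreground classes
        gdice = np.zeros_like(p)
        dls, active = [], []
        for cls in w.foreground_classes:
            if not onehot[cls].any():
                continue
            inter = float((p[cls] * onehot[cls]).sum())
            size = float(p[cls].sum() + onehot[cls].sum())
            denom = size + w.epsilon
            dls.append(1.0 - (2.0 * inter + w.epsilon) / denom)
            gdice[cls] = -(2.0 * onehot[cls] * denom - (2.0 * inter + w.epsilon)) / denom ** 2
            active.append(cls)
        if dls:
            total += float(np.mean(dls))
            gdice /= len(dls)
        grad[i] = gfocal + gdice
    total /= idx.size
    grad /= idx.size
    return total, grad.astype(np.float32)


def vae_grad(target: np.ndarray, recon: np.ndarray, mu: np.ndarray,
             log_var: np.ndarray):
    """Batched VAE loss and gradients (w.r.t. recon, mu, log_var)."""
    diff = recon.astype(np.float64) - target
    mse = float((diff ** 2).mean())
    d_recon = (2.0 * diff / diff.size).astype(np.float32)
    n = mu.shape[0]
    kl = float((0.5 * (mu.astype(np.float64) ** 2 + np.exp(log_var)
                       - log_var - 1.0)).sum() / n)
    d_mu = (mu / n).astype(np.float32)
    d_lv = (0.5 * (np.exp(log_var) - 1.0) / n).astype(np.float32)
    return mse + kl, d_recon, d_mu, d_lv
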