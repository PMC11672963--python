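"""Two-stage training: self-supervised pre-training and semi-supervised
fine-tuning with the annotation-budget-adaptive learning-rate policy.

Stage 1 (pretrain): random patches are cropped from (unannotated) images,
twin hole-masked views are built, and the reconstruction network minimizes
L_self = L_con + L_rec with Adam.  The best model is selected by validation
loss on a held-out fraction of the images.

Stage 2 (train_semisupervised): the pre-trained trunk is transferred into
the segmentation network, whose parameters are split into two optimizer
groups — transferred layers at LR1, randomly initialized layers (softmax
head, VAE branch) at LR2 = beta * LR1, where beta = f(n) falls from 20 with
a single annotated image to 0.02 with the full 42-image budget.  Each AdamW
step mixes labeled and unlabeled samples (half/half by default): the Dice
focal loss sees only labeled rows, the VAE term sees every row.  The best
model is selected by mean foreground DSC on the held-out labeled validation
split.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import losses as L
from ._nn import Adam
from .metrics import dsc
from .networks import ReconstructionNet, SegmentationNet, save_checkpoint
from .patching import MaskConfig, make_pretrain_pair, random_crop

__all__ = ["LRPolicy", "TrainConfig", "beta_for_n", "pretrain",
           "build_param_groups", "train_semisupervised"]

DEFAULT_BETA_TABLE = ((42, 0.02), (21, 0.2), (12, 2.0), (4, 10.0), (1, 20.0))


@dataclass
class LRPolicy:
    lr1: float = 1e-4
    beta_table: tuple = DEFAULT_BETA_TABLE
    n_labeled: int = 42

    @property
    def beta(self) -> float:
        return beta_for_n(self.n_labeled, self.beta_table)

    @property
    def lr2(self) -> float:
        return self.beta * self.lr1


def beta_for_n(n: int, table=DEFAULT_BETA_TABLE) -> float:
    """Learning-rate ratio beta = LR2/LR1 as a function of the number of
    annotated training samples n.

    Exact at the tabulated points; log-linear interpolation in
    (log n, log beta) between them (the ratio spans three orders of
    magnitude, so log-log is the natural monotone fit); clamped to the
    nearest endpoint outside the table's range.
    """
    if n < 1:
        raise ValueError("the annotated sample count must be at least 1")
    pts = sorted(table)  # ascending in n
    ns = np.array([p[0] for p in pts], dtype=float)
    betas = np.array([p[1] for p in pts], dtype=float)
    if n <= ns[0]:
        return float(betas[0])
    if n >= ns[-1]:
        return float(betas[-1])
    logb = np.interp(np.log(n), np.log(ns), np.log(betas))
    return float(np.exp(logb))


@dataclass
class TrainConfig:
    stage: str = "segment"            # "pretrain" | "segment"
    optimizer: str = "adamw"          # Adam for pretraining, AdamW for segmentation
    lr: float = 1e-4
    epochs: int = 100
    batch_size: int = 16
    val_fraction: float = 0.2
    seed: int = 0
    checkpoint_every: int = 0         # 0: only the final/best checkpoint
    crop_size: int = 64               # pretraining patch size
    weight_decay: float = 1e-2        # AdamW only
    mask: MaskConfig = field(default_factory=MaskConfig)
    loss: L.LossWeights = field(default_factory=L.LossWeights)

    def __post_init__(self):
        if not (0.0 < self.val_fraction < 1.0):
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.stage not in ("pretrain", "segment"):
            raise ValueError("stage must be 'pretrain' or 'segment'")


def _snapshot(net):
    return ([p.data.copy() for p in net.parameters()],
            [(bn.running_mean.copy(), bn.running_var.copy())
             for bn in net.trunk.bn_layers()])


def _restore(net, snap):
    params, stats = snap
    for p, d in zip(net.parameters(), params):
        p.data[...] = d
    for bn, (m, v) in zip(net.trunk.bn_layers(), stats):
        bn.running_mean[...] = m
        bn.running_var[...] = v


def _l1_grads(r1, r2, x):
    """Gradients of mean|r1-r2| + mean|r1-x| + mean|r2-x| w.r.t. r1 and r2."""
    npix = r1.size
    d1 = (np.sign(r1 - r2) + np.sign(r1 - x)) / npix
    d2 = (np.sign(r2 - r1) + np.sign(r2 - x)) / npix
    return d1.astype(np.float32), d2.astype(np.float32)


def pretrain(images, net: ReconstructionNet, config: TrainConfig,
             out_ckpt=None) -> tuple[ReconstructionNet, pd.DataFrame]:
    """Self-supervised pre-training on a pool of (unannotated) images.

    ``images`` is a sequence of 2D arrays in [0,1].  Returns the network at
    its best-validation-loss state and the per-epoch history; deterministic
    given ``config.seed`` up to floating-point reduction order.
    """
    images = [np.asarray(im, dtype=np.float32) for im in images]
    if not images:
        raise ValueError("pre-training needs at least one image")
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(images))
    n_val = min(max(1, int(round(config.val_fraction * len(images)))), len(images) - 1) \
        if len(images) > 1 else 0
    val_idx, train_idx = order[:n_val], order[n_val:]

    # fixed validation pairs so epochs are comparable
    val_pairs = [make_pretrain_pair(random_crop(images[i], config.crop_size, 7_000 + i),
                                    config.mask, 9_000 + i) for i in val_idx]

    opt = Adam([{"params": net.parameters(), "lr": config.lr}])
    history, best = [], (math.inf, None)
    bs = max(1, config.batch_size)
    step_seed = np.random.default_rng(config.seed + 1)
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(train_idx)
        ep_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), bs):
            idx = perm[start : start + bs]
            seeds = step_seed.integers(0, 2 ** 31 - 1, size=2 * len(idx))
            pairs = [make_pretrain_pair(
                random_crop(images[i], config.crop_size, int(seeds[2 * j])),
                config.mask, int(seeds[2 * j + 1])) for j, i in enumerate(idx)]
            x = np.stack([p.original for p in pairs])[:, None]
            v = np.concatenate([np.stack([p.view1 for p in pairs]),
                                np.stack([p.view2 for p in pairs])])[:, None]
            opt.zero_grad()
            r = net.forward(v, train=True)
            r1, r2 = r[: len(idx)], r[len(idx):]
            loss = (float(np.abs(r1 - r2).mean()) + float(np.abs(r1 - x).mean())
                    + float(np.abs(r2 - x).mean()))
            d1, d2 = _l1_grads(r1, r2, x)
            net.backward(np.concatenate([d1, d2]))
            opt.step()
            ep_loss += loss
            n_batches += 1
        train_loss = ep_loss / max(n_batches, 1)
        val_loss = _pretrain_val_loss(net, val_pairs) if val_pairs else train_loss
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if val_loss < best[0]:
            best = (val_loss, _snapshot(net))
    if best[1] is not None:
        _restore(net, best[1])
    hist = pd.DataFrame(history)
    if out_ckpt is not None:
        save_checkpoint(out_ckpt, net, extra={"stage": "pretrain",
                                              "best_val_loss": best[0]})
    return net, hist


def _pretrain_val_loss(net, val_pairs) -> float:
    x = np.stack([p.original for p in val_pairs])[:, None]
    v1 = np.stack([p.view1 for p in val_pairs])[:, None]
    v2 = np.stack([p.view2 for p in val_pairs])[:, None]
    r1 = net.forward(v1, train=False)
    r2 = net.forward(v2, train=False)
    return (float(np.abs(r1 - r2).mean()) + float(np.abs(r1 - x).mean())
            + float(np.abs(r2 - x).mean()))


def build_param_groups(seg_net: SegmentationNet, policy: LRPolicy,
                       transfer_report: dict | None) -> list[dict]:
    """Two optimizer groups: transferred parameters at LR1, randomly
    initialized ones at LR2 = beta(n) * LR1.  Without a transfer report
    (training from scratch) every parameter runs at LR1."""
    params = seg_net.parameters()
    if transfer_report is None:
        return [{"params": params, "lr": policy.lr1}]
    groups = {"transferred": [], "random": []}
    for p in params:
        status = transfer_report.get(p.name)
        if status not in groups:
            raise KeyError(f"parameter {p.name} missing from the transfer report")
        groups[status].append(p)
    return [{"params": groups["transferred"], "lr": policy.lr1},
            {"params": groups["random"], "lr": policy.lr2}]


def _val_dsc(net, val_set) -> float:
    scores = []
    for image, label in val_set:
        out = net.forward(image[None], train=False)
        pred = out["probs"][0].argmax(axis=0)
        per_class = [dsc(pred == c, label == c) for c in (1, 2, 3) if (label == c).any()]
        if per_class:
            scores.append(float(np.mean(per_class)))
    return float(np.mean(scores)) if scores else 0.0


def train_semisupervised(labeled, unlabeled, seg_net: SegmentationNet,
                         config: TrainConfig, policy: LRPolicy,
                         transfer_report: dict | None = None,
                         out_ckpt=None):
    """Semi-supervised fine-tuning.

    ``labeled``: sequence of (image, label) pairs; ``unlabeled``: sequence of
    images (may be empty, which degenerates to supervised training with the
    VAE term on labeled data only).  Returns (net, history DataFrame); the
    returned network carries the best-validation-DSC parameters.
    """
    labeled = [(np.asarray(im, dtype=np.float32), np.asarray(lab)) for im, lab in labeled]
    unlabeled = [np.asarray(im, dtype=np.float32) for im in unlabeled]
    if not labeled:
        raise ValueError("semi-supervised training requires at least one labeled sample")

    rng = np.random.default_rng(config.seed)
    order = rng.permutation(len(labeled))
    if len(labeled) >= 2:
        n_val = min(max(1, int(round(config.val_fraction * len(labeled)))),
                    len(labeled) - 1)
        val_set = [labeled[i] for i in order[:n_val]]
        train_set = [labeled[i] for i in order[n_val:]]
    else:
        val_set, train_set = labeled, labeled

    groups = build_param_groups(seg_net, policy, transfer_report)
    decoupled = config.optimizer.lower() == "adamw"
    opt = Adam(groups, weight_decay=config.weight_decay if decoupled else 0.0,
               decoupled=decoupled)

    half = max(1, config.batch_size // 2) if unlabeled else config.batch_size
    net_rng = np.random.default_rng(config.seed + 13)
    history, best = [], (-1.0, None)
    for epoch in range(1, config.epochs + 1):
        perm = rng.permutation(len(train_set))
        ep = {"dfl": 0.0, "vae": 0.0, "n": 0}
        for start in range(0, len(perm), half):
            lab_idx = perm[start : start + half]
            batch_imgs = [train_set[i][0] for i in lab_idx]
            batch_labels = [train_set[i][1] for i in lab_idx]
            n_lab = len(batch_imgs)
            if unlabeled:
                u_idx = rng.integers(0, len(unlabeled), size=half)
                batch_imgs += [unlabeled[i] for i in u_idx]
            x = np.stack(batch_imgs)[:, None]
            labels = np.zeros((len(batch_imgs),) + batch_imgs[0].shape, dtype=np.int64)
            labels[:n_lab] = np.stack(batch_labels)
            labeled_mask = np.zeros(len(batch_imgs), dtype=bool)
            labeled_mask[:n_lab] = True

            opt.zero_grad()
            out = seg_net.forward(x, train=True, rng=net_rng)
            dfl, d_probs = L.dice_focal_grad(out["probs"], labels, config.loss,
                                             labeled_mask)
            vloss, d_recon, d_mu, d_lv = L.vae_grad(
                out["vae_target"], out["vae_recon"],
                out["latent"].mu, out["latent"].log_var)
            seg_net.backward(d_probs, d_recon, d_mu, d_lv)
            opt.step()
            ep["dfl"] += dfl
            ep["vae"] += vloss
            ep["n"] += 1
        n = max(ep["n"], 1)
        val_score = _val_dsc(seg_net, val_set)
        history.append({"epoch": epoch, "dfl": ep["dfl"] / n, "vae": ep["vae"] / n,
                        "total": (ep["dfl"] + ep["vae"]) / n, "val_dsc": val_score})
        if val_score > best[0]:
            best = (val_score, _snapshot(seg_net))
    if best[1] is not None:
        _restore(seg_net, best[1])
    hist = pd.DataFrame(history)
    if out_ckpt is not None:
        save_checkpoint(out_ckpt, seg_net,
                        extra={"stage": "segment", "best_val_dsc": best[0]})
    return seg_net, hist
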