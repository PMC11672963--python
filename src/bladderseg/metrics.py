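"""Segmentation evaluation: DSC, sensitivity, specificity, Hausdorff distance.

All metrics are computed per class on binary masks S (prediction) and G
(ground truth).  DSC = 2|S∩G| / (|S| + |G|); SEN = TP/(TP+FN);
SPE = TN/(TN+FP); HD is the symmetric Hausdorff distance between the two
boundary point sets in Euclidean pixel units (an optional spacing multiplier
converts to mm).  Conventions at empty masks: DSC is 1 when both masks are
empty; SEN/SPE return 1 on an empty denominator; HD is undefined (error) on
an empty mask.  ``evaluate`` aggregates per class across a test set,
excluding cases whose ground truth lacks the class from that class's average.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial.distance import directed_hausdorff

__all__ = ["MetricsReport", "dsc", "sensitivity", "specificity", "hausdorff",
           "evaluate", "CLASS_NAMES"]

CLASS_NAMES = {0: "background", 1: "urine", 2: "wall", 3: "tumor"}


def _as_bool(S, G):
    S, G = np.asarray(S).astype(bool), np.asarray(G).astype(bool)
    if S.shape != G.shape:
        raise ValueError(f"mask shapes differ: {S.shape} vs {G.shape}")
    return S, G


def dsc(S, G) -> float:
    """Dice similarity coefficient 2|S∩G| / (|S| + |G|); 1 if both empty."""
    S, G = _as_bool(S, G)
    denom = S.sum() + G.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(S, G).sum() / denom)


def sensitivity(S, G) -> float:
    """True-positive rate TP/(TP+FN); 1 when the ground truth is empty."""
    S, G = _as_bool(S, G)
    tp = np.logical_and(S, G).sum()
    fn = np.logical_and(~S, G).sum()
    return 1.0 if tp + fn == 0 else float(tp / (tp + fn))


def specificity(S, G) -> float:
    """True-negative rate TN/(TN+FP); 1 when the ground truth covers everything."""
    S, G = _as_bool(S, G)
    tn = np.logical_and(~S, ~G).sum()
    fp = np.logical_and(S, ~G).sum()
    return 1.0 if tn + fp == 0 else float(tn / (tn + fp))


def _boundary(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=np.ones((3, 3)), border_value=0)
    return np.argwhere(mask & ~eroded)


def hausdorff(S, G, spacing: float = 1.0) -> float:
    """Symmetric Hausdorff distance between boundary point sets (pixel units)."""
    S, G = _as_bool(S, G)
    if not S.any() or not G.any():
        raise ValueError("Hausdorff distance is undefined for an empty mask")
    bs, bg = _boundary(S), _boundary(G)
    d = max(directed_hausdorff(bs, bg)[0], directed_hausdorff(bg, bs)[0])
    return float(d * spacing)


@dataclass
class MetricsReport:
    per_case: pd.DataFrame
    per_class: pd.DataFrame
    mean_foreground: dict = field(default_factory=dict)

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)

    def summary(self) -> dict:
        return {
            "per_class": {r["class_name"]: {k: r[k] for k in ("dsc", "sen", "spe", "hd")}
                          for _, r in self.per_class.iterrows()},
            "mean_foreground": self.mean_foreground,
        }


def evaluate(predictions, ground_truths, classes=(1, 2, 3),
             spacing: float = 1.0, case_ids=None) -> MetricsReport:
    """Per-class metrics for paired label maps, averaged across cases.

    A case whose ground truth lacks a class is excluded from that class's
    averages; HD is additionally skipped when the prediction of a present
    class is empty (it is undefined there — such cases still pull DSC/SEN
    down).
    """
    predictions, ground_truths = list(predictions), list(ground_truths)
    if len(predictions) != len(ground_truths):
        raise ValueError("predictions and ground truths must pair up")
    case_ids = case_ids or list(range(len(predictions)))
    rows = []
    for cid, pred, gt in zip(case_ids, predictions, ground_truths):
        pred, gt = np.asarray(pred), np.asarray(gt)
        if pred.shape != gt.shape:
            raise ValueError(f"case {cid}: shape mismatch {pred.shape} vs {gt.shape}")
        for c in classes:
            if not (gt == c).any():
                continue
            S, G = pred == c, gt == c
            hd = hausdorff(S, G, spacing) if S.any() else np.nan
            rows.append({
                "case_id": cid, "class": c, "class_name": CLASS_NAMES.get(c, str(c)),
                "dsc": dsc(S, G), "sen": sensitivity(S, G),
                "spe": specificity(S, G), "hd": hd,
                "gt_pixels": int(G.sum()), "pred_pixels": int(S.sum()),
            })
    per_case = pd.DataFrame(rows)
    if per_case.empty:
        raise ValueError("no evaluable class/case pairs")
    per_class = (per_case.groupby(["class", "class_name"], as_index=False)
                 [["dsc", "sen", "spe", "hd"]].mean())
    mean_fg = {k: float(per_class[k].mean()) for k in ("dsc", "sen", "spe", "hd")}
    return MetricsReport(per_case=per_case, per_class=per_class,
                         mean_foreground=mean_fg)
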