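"""Test-time augmentation and anatomical segmentation correction.

TTA: the test image is pushed through a set of exactly invertible grid
transforms (flips, quarter-turn rotations), segmented, inverse-transformed
back to the original frame, and the probability maps are merged (mean by
default, majority vote optionally).  Restricting the augmentations to
exact-invertible ops means inverse(forward(x)) == x bitwise, so merging
introduces no resampling blur.

Correction: a bladder image contains one bladder, whose urine/wall/tumor
union is a single region without interior background.  Predictions are
corrected toward that prior by keeping the largest connected foreground
component (8-connected) and filling interior background holes (4-connected
hole detection), each filled pixel inheriting the majority class of its
foreground neighbors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "TTATransform", "CorrectionReport", "default_transforms", "register_transform",
    "tta_predict", "largest_component", "fill_holes", "correct_segmentation",
    "count_components", "predict",
]

FOREGROUND_CLASSES = (1, 2, 3)
_STRUCT8 = np.ones((3, 3), dtype=bool)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass(frozen=True)
class TTATransform:
    """An invertible spatial transform applied along the channel-last axes."""
    name: str
    forward: callable
    inverse: callable


def _rot(k):
    return (lambda x, k=k: np.rot90(x, k, axes=(-2, -1)).copy(),
            lambda x, k=k: np.rot90(x, -k, axes=(-2, -1)).copy())


_TRANSFORMS: dict[str, TTATransform] = {}


def register_transform(t: TTATransform, probe_shape=(6, 8)) -> TTATransform:
    """Register a transform after verifying inverse(forward(x)) == x exactly."""
    probe = np.arange(np.prod(probe_shape)).reshape(probe_shape)
    back = t.inverse(t.forward(probe))
    if back.shape != probe.shape or not np.array_equal(back, probe):
        raise ValueError(f"transform {t.name!r} is not exactly invertible")
    _TRANSFORMS[t.name] = t
    return t


for _name, (_f, _i) in {
    "identity": (lambda x: x.copy(), lambda x: x.copy()),
    "hflip": (lambda x: x[..., :, ::-1].copy(),) * 2,
    "vflip": (lambda x: x[..., ::-1, :].copy(),) * 2,
    "rot90": _rot(1),
    "rot180": _rot(2),
    "rot270": _rot(3),
}.items():
    register_transform(TTATransform(_name, _f, _i), probe_shape=(8, 8))


def default_transforms(names=None) -> list[TTATransform]:
    names = names or ["identity", "hflip", "vflip", "rot90", "rot180", "rot270"]
    return [_TRANSFORMS[n] for n in names]


def tta_predict(model, image: np.ndarray, transforms: list[TTATransform],
                merge: str = "mean") -> np.ndarray:
    """Merged class-probability map over the augmented views.

    ``merge="mean"`` averages the inverse-transformed probability maps;
    ``merge="vote"`` takes the per-pixel majority of the per-view argmax
    labels (returned as a one-hot-like probability map, ties toward the
    lower class index).
    """
    if not transforms:
        raise ValueError("transform list must be non-empty")
    from .networks import segment_forward

    maps = []
    for t in transforms:
        probs, _, _ = segment_forward(t.forward(np.asarray(image)), model)
        maps.append(t.inverse(probs))
    stack = np.stack(maps)
    if merge == "mean":
        merged = stack.mean(axis=0)
        return (merged / merged.sum(axis=0, keepdims=True)).astype(np.float32)
    if merge == "vote":
        votes = stack.argmax(axis=1)  # (T, H, W)
        c = stack.shape[1]
        counts = np.stack([(votes == k).sum(axis=0) for k in range(c)])
        winner = counts.argmax(axis=0)
        return np.eye(c, dtype=np.float32)[winner].transpose(2, 0, 1)
    raise ValueError(f"unknown merge rule {merge!r}")


def count_components(label: np.ndarray, connectivity: int = 8) -> int:
    structure = _STRUCT8 if connectivity == 8 else _STRUCT4
    return ndimage.label(np.isin(label, FOREGROUND_CLASSES), structure=structure)[1]


def largest_component(label: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the largest connected component of the foreground union.

    Components are computed over the union of classes {1,2,3}; every other
    component is relabeled background while class identities inside the kept
    component are preserved.  Ties go to the first component in row-major
    order (scipy labels in scan order).  An all-background map is returned
    unchanged with a warning.
    """
    label = np.asarray(label)
    fg = np.isin(label, FOREGROUND_CLASSES)
    structure = _STRUCT8 if connectivity == 8 else _STRUCT4
    comps, n = ndimage.label(fg, structure=structure)
    if n == 0:
        warnings.warn("no foreground to correct", stacklevel=2)
        return label.copy()
    if n == 1:
        return label.copy()
    sizes = ndimage.sum_labels(np.ones_like(comps), comps, index=np.arange(1, n + 1))
    keep = int(np.argmax(sizes)) + 1  # argmax -> first maximal, row-major
    out = label.copy()
    out[(comps != keep) & fg] = 0
    return out


def fill_holes(label: np.ndarray, connectivity: int = 4):
    """Fill interior background holes of the foreground union.

    A hole is background not connected to the image border (4-connected by
    default).  Each hole pixel takes the majority class among its nearest
    labeled neighbors, assigned iteratively from the hole boundary inward;
    foreground pixels never change class.
    """
    label = np.asarray(label).copy()
    fg = np.isin(label, FOREGROUND_CLASSES)
    structure = _STRUCT4 if connectivity == 4 else _STRUCT8
    filled = ndimage.binary_fill_holes(fg, structure=structure)
    holes = filled & ~fg
    n_filled = int(holes.sum())
    while holes.any():
        # majority class of 8-neighboring labeled pixels, one ring at a time
        boundary = holes & (ndimage.binary_dilation(~holes & (label > 0), _STRUCT8))
        if not boundary.any():  # pragma: no cover - defensive
            break
        votes = np.zeros((4,) + label.shape, dtype=np.int32)
        for c in FOREGROUND_CLASSES:
            votes[c] = ndimage.convolve((label == c).astype(np.int32),
                                        np.ones((3, 3), dtype=np.int32), mode="constant")
        choice = votes[:, boundary].argmax(axis=0)
        ys, xs = np.nonzero(boundary)
        label[ys, xs] = choice
        holes &= ~boundary
    return label


@dataclass
class CorrectionReport:
    components_removed: int = 0
    hole_pixels_filled: int = 0
    changed_pixel_fraction: float = 0.0

    def to_dict(self) -> dict:
        return {"components_removed": self.components_removed,
                "hole_pixels_filled": self.hole_pixels_filled,
                "changed_pixel_fraction": self.changed_pixel_fraction}


def correct_segmentation(label: np.ndarray):
    """Largest-component filtering followed by hole filling.

    The output's foreground union is a single connected, hole-free region
    (when any foreground exists), and the operation is idempotent.
    """
    label = np.asarray(label)
    n_before = count_components(label)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kept = largest_component(label)
    removed = max(n_before - 1, 0)
    fg_before = np.isin(kept, FOREGROUND_CLASSES)
    filled = fill_holes(kept)
    holes_filled = int((np.isin(filled, FOREGROUND_CLASSES) & ~fg_before).sum())
    changed = float((filled != label).mean())
    return filled, CorrectionReport(components_removed=removed,
                                    hole_pixels_filled=holes_filled,
                                    changed_pixel_fraction=changed)


def predict(model, image: np.ndarray, tta: bool = True, correct: bool = True,
            merge: str = "mean", transforms: list[TTATransform] | None = None):
    """Full inference: (optional) TTA -> per-pixel argmax -> (optional) correction.

    Argmax ties break toward the lower class index (numpy argmax convention).
    Returns (LabelMap, CorrectionReport).
    """
    transforms = transforms if transforms is not None else (
        default_transforms() if tta else default_transforms(["identity"]))
    if not tta:
        transforms = default_transforms(["identity"])
    probs = tta_predict(model, image, transforms, merge=merge)
    label = probs.argmax(axis=0).astype(np.int64)
    if not correct:
        return label, CorrectionReport()
    return correct_segmentation(label)
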