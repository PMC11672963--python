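"""Synthetic bladder phantoms.

The clinical T2-weighted MRI cohort behind this method is not public, so the
package ships a generator of 2D phantoms carrying the statistical structure
the method assumes: exactly one bladder per image — a bright urine-filled
lumen (random ellipse), a thin dark muscular wall (a closed Euclidean ring
around the lumen), and, in most samples, a wall-attached tumor (a star-shaped
blob grown from a random wall pixel) whose intensity lies between wall and
urine, so that wall/tumor discrimination is genuinely ambiguous after
boundary blurring and additive noise — the difficulty that motivates the
method.  Class codes: 0 background, 1 urine, 2 wall, 3 tumor.
"""

from __future__ import annotations

import shutil
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import io

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom", "generate_dataset"]

FOREGROUND_CLASSES = (1, 2, 3)


@dataclass
class PhantomConfig:
    image_size: int = 96
    lumen_radius_range: tuple[float, float] = (0.16, 0.26)  # fraction of image size
    wall_thickness_range: tuple[int, int] = (3, 6)          # pixels
    tumor_radius_range: tuple[int, int] = (5, 10)           # pixels
    intensity_means: dict = field(default_factory=lambda: {
        "background": 0.10, "urine": 0.85, "wall": 0.25, "tumor": 0.45})
    noise_sigma: float = 0.03
    blur_sigma: float = 1.0
    tumor_probability: float = 0.9

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        for name in ("lumen_radius_range", "wall_thickness_range", "tumor_radius_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be a non-degenerate positive range")
        m = self.intensity_means
        if not (m["urine"] > m["tumor"] > m["wall"]):
            raise ValueError("intensity ordering must be urine > tumor > wall "
                             "(T2-like contrast)")

    @property
    def class_means(self) -> np.ndarray:
        m = self.intensity_means
        return np.array([m["background"], m["urine"], m["wall"], m["tumor"]],
                        dtype=np.float64)


@dataclass
class PhantomSample:
    image: np.ndarray
    label: np.ndarray
    has_tumor: bool
    seed: int


def _star_blob(shape, center, radius, rng) -> np.ndarray:
    """Star-convex blob: a disk whose radius is modulated by low-order harmonics."""
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    dy, dx = yy - center[0], xx - center[1]
    theta = np.arctan2(dy, dx)
    r_mod = np.ones_like(theta)
    for k in (2, 3, 4):
        r_mod += rng.uniform(0.05, 0.15) * np.cos(k * theta + rng.uniform(0, 2 * np.pi))
    return dy ** 2 + dx ** 2 <= (radius * r_mod) ** 2


def generate_phantom(config: PhantomConfig, seed: int) -> PhantomSample:
    """Generate one phantom, deterministically from (config, seed).

    The tumor blob is grown from a point on the wall and replaces the
    wall/lumen pixels it covers; the foreground union {urine, wall, tumor}
    is guaranteed to be one hole-free connected component.
    """
    size = config.image_size
    rng = np.random.default_rng(seed)

    lumen_lo, lumen_hi = config.lumen_radius_range
    t_lo, t_hi = config.wall_thickness_range
    tumor_hi = config.tumor_radius_range[1]
    if t_hi >= lumen_lo * size:
        raise ValueError(
            f"wall thickness up to {t_hi}px exceeds the smallest lumen radius "
            f"{lumen_lo * size:.1f}px; thin the wall or enlarge the lumen")

    thickness = int(rng.integers(t_lo, t_hi + 1))
    margin = thickness + tumor_hi + 2
    max_axis = size / 2 - margin
    a = min(rng.uniform(lumen_lo, lumen_hi) * size, max_axis)
    b = min(rng.uniform(lumen_lo, lumen_hi) * size, max_axis)
    a = max(a, t_hi + 2)
    b = max(b, t_hi + 2)
    jitter = max(size / 2 - max(a, b) - margin, 0.0)
    cy = size / 2 + rng.uniform(-jitter, jitter)
    cx = size / 2 + rng.uniform(-jitter, jitter)
    angle = rng.uniform(0, np.pi)

    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    lumen = (u / a) ** 2 + (v / b) ** 2 <= 1.0

    # closed ring of Euclidean thickness `thickness` around the lumen
    outer = ndimage.distance_transform_edt(~lumen) <= thickness
    label = np.zeros((size, size), dtype=np.int64)
    label[outer] = 2
    label[lumen] = 1

    has_tumor = bool(rng.random() < config.tumor_probability)
    if has_tumor:
        wall_pixels = np.argwhere(label == 2)
        center = wall_pixels[rng.integers(len(wall_pixels))]
        radius = rng.uniform(*config.tumor_radius_range)
        blob = _star_blob((size, size), center, radius, rng)
        label[blob] = 3
        if not (label == 2).any():  # pragma: no cover - geometry forbids it
            raise RuntimeError("tumor consumed the entire wall")

    # enforce the hole-free foreground invariant the anatomy implies
    from .inference import fill_holes
    label = fill_holes(label)

    image = config.class_means[label]
    if config.blur_sigma > 0:
        image = ndimage.gaussian_filter(image, config.blur_sigma)
    image = image + rng.normal(0.0, config.noise_sigma, image.shape)
    image = np.clip(image, 0.0, 1.0).astype(np.float32)
    return PhantomSample(image=image, label=label, has_tumor=has_tumor, seed=seed)


def generate_dataset(n_labeled: int, n_unlabeled: int, n_test: int,
                     config: PhantomConfig, seed: int, out_dir,
                     overwrite: bool = False, nifti: bool = False) -> dict:
    """Write a labeled/unlabeled/test phantom dataset and its JSON manifest.

    Labels are written for the labeled and test splits only.  Per-sample
    seeds are drawn once from the master seed, so the manifest (and every
    pixel) is reproducible.  Refuses to write into a non-empty directory
    unless ``overwrite`` is set.
    """
    if min(n_labeled, n_unlabeled, n_test) < 0:
        raise ValueError("split sizes must be non-negative")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()):
        if not overwrite:
            raise FileExistsError(
                f"{out_dir} is not empty; pass overwrite=True to replace it")
        shutil.rmtree(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    master = np.random.default_rng(seed)
    total = n_labeled + n_unlabeled + n_test
    sample_seeds = master.integers(0, 2 ** 31 - 1, size=total)

    splits = {"labeled": [], "unlabeled": [], "test": []}
    plan = ([("labeled", True)] * n_labeled + [("unlabeled", False)] * n_unlabeled
            + [("test", True)] * n_test)
    counters = {k: 0 for k in splits}
    for (split, labeled), s in zip(plan, sample_seeds):
        sample = generate_phantom(config, int(s))
        i = counters[split]
        counters[split] += 1
        sub = out_dir / split
        sub.mkdir(exist_ok=True)
        img_rel = f"{split}/img_{i:04d}.png"
        io.write_image_png(out_dir / img_rel, sample.image)
        entry = {"image": img_rel, "seed": int(s), "has_tumor": sample.has_tumor}
        if labeled:
            lab_rel = f"{split}/lab_{i:04d}.png"
            io.write_label_png(out_dir / lab_rel, sample.label)
            entry["label"] = lab_rel
        if nifti:
            nii_rel = f"{split}/img_{i:04d}.nii.gz"
            io.write_nifti(out_dir / nii_rel, sample.image)
            entry["nifti"] = nii_rel
        splits[split].append(entry)

    manifest = {
        "seed": seed,
        "config": asdict(config),
        "splits": splits,
        "counts": {k: len(v) for k, v in splits.items()},
    }
    io.write_manifest(out_dir, manifest)
    return manifest
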