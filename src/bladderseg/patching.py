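"""Random cropping and hole-noise masking for self-supervised pre-training.

A training example is built by randomly cropping a square patch from an
image, then producing two *different* masked views of that same patch: each
view independently samples 5-10 axis-aligned square holes with side 15-20
pixels and replaces the pixels inside them with noise.  The twin views feed
the reconstruction network, whose contrast-consistency loss ties their
reconstructions together while the reconstruction-observation loss ties both
to the unmasked original.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HoleSpec", "PretrainPair", "MaskConfig", "random_crop",
           "sample_holes", "apply_mask", "make_pretrain_pair"]


@dataclass(frozen=True)
class HoleSpec:
    """A square hole: top-left corner (row, col) and side length in pixels."""
    row: int
    col: int
    side: int


@dataclass
class MaskConfig:
    holes_min: int = 5
    holes_max: int = 10
    side_min: int = 15
    side_max: int = 20
    noise: str = "uniform"  # or "gaussian"

    def __post_init__(self):
        if not (0 <= self.holes_min <= self.holes_max):
            raise ValueError("hole count range must satisfy 0 <= min <= max")
        if not (0 < self.side_min <= self.side_max):
            raise ValueError("hole side range must satisfy 0 < min <= max")
        if self.noise not in ("uniform", "gaussian"):
            raise ValueError("noise must be 'uniform' or 'gaussian'")


@dataclass
class PretrainPair:
    original: np.ndarray
    view1: np.ndarray
    view2: np.ndarray
    holes1: list[HoleSpec]
    holes2: list[HoleSpec]


def random_crop(image: np.ndarray, size: int, seed: int) -> np.ndarray:
    """Crop a size x size window at a uniformly random valid offset."""
    image = np.asarray(image)
    h, w = image.shape[-2:]
    if size > h or size > w:
        raise ValueError(f"crop size {size} exceeds image size {h}x{w}")
    rng = np.random.default_rng(seed)
    r = int(rng.integers(0, h - size + 1))
    c = int(rng.integers(0, w - size + 1))
    return image[..., r : r + size, c : c + size].copy()


def sample_holes(n_min: int, n_max: int, s_min: int, s_max: int,
                 patch_size: int, seed: int) -> list[HoleSpec]:
    """Sample a hole set: count uniform in [n_min, n_max], side uniform in
    [s_min, s_max], positions uniform with the hole fully inside the patch."""
    if s_max >= patch_size:
        raise ValueError(
            f"maximum hole side {s_max} cannot fit inside a {patch_size}px patch")
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    holes = []
    for _ in range(n):
        side = int(rng.integers(s_min, s_max + 1))
        row = int(rng.integers(0, patch_size - side + 1))
        col = int(rng.integers(0, patch_size - side + 1))
        holes.append(HoleSpec(row=row, col=col, side=side))
    return holes


def apply_mask(patch: np.ndarray, holes: list[HoleSpec], seed: int,
               noise: str = "uniform") -> np.ndarray:
    """Replace the pixels inside each hole with noise; overlaps overwrite.

    Uniform noise on [0,1] by default (maximal corruption entropy within the
    valid intensity range); Gaussian(0.5, 0.25) clipped to [0,1] optionally.
    Pixels outside the holes are untouched.
    """
    patch = np.asarray(patch, dtype=np.float32)
    out = patch.copy()
    h, w = patch.shape
    rng = np.random.default_rng(seed)
    for hole in holes:
        if hole.row < 0 or hole.col < 0 or hole.row + hole.side > h or hole.col + hole.side > w:
            raise ValueError(f"hole {hole} lies outside the {h}x{w} patch")
        if noise == "uniform":
            fill = rng.random((hole.side, hole.side), dtype=np.float32)
        else:
            fill = np.clip(rng.normal(0.5, 0.25, (hole.side, hole.side)), 0, 1)
        out[hole.row : hole.row + hole.side, hole.col : hole.col + hole.side] = fill
    return np.clip(out, 0.0, 1.0)


def make_pretrain_pair(patch: np.ndarray, mask_config: MaskConfig | None,
                       seed: int) -> PretrainPair:
    """Two independently masked views of the same (already cropped) patch."""
    cfg = mask_config or MaskConfig()
    patch = np.asarray(patch, dtype=np.float32)
    size = patch.shape[0]
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2 ** 31 - 1, size=4)
    views, hole_sets = [], []
    for hole_seed, noise_seed in (sub[:2], sub[2:]):
        if cfg.holes_min == cfg.holes_max == 0:
            holes = []
        else:
            holes = sample_holes(cfg.holes_min, cfg.holes_max, cfg.side_min,
                                 cfg.side_max, size, int(hole_seed))
        hole_sets.append(holes)
        views.append(apply_mask(patch, holes, int(noise_seed), cfg.noise))
    return PretrainPair(original=patch, view1=views[0], view2=views[1],
                        holes1=hole_sets[0], holes2=hole_sets[1])
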