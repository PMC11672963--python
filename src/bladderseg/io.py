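"""Reading and writing images, label maps, and dataset manifests.

Images travel as 8-bit grayscale PNG (intensities in [0,1] scaled to 0..255);
label maps as PNG with the class index {0: background, 1: urine, 2: wall,
3: tumor} stored directly as the pixel value.  Either can optionally be
exported as single-slice NIfTI with an identity affine.  A dataset on disk is
described by a JSON manifest mapping each split to its image/label files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

MANIFEST_NAME = "manifest.json"


def write_image_png(path, image: np.ndarray) -> None:
    arr = np.clip(np.asarray(image, dtype=np.float64), 0.0, 1.0)
    Image.fromarray(np.round(arr * 255).astype(np.uint8), mode="L").save(path)


def read_image_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(path).convert("L"), dtype=np.float32)
    return arr / 255.0


def write_label_png(path, label: np.ndarray) -> None:
    lab = np.asarray(label)
    if lab.min() < 0 or lab.max() > 255:
        raise ValueError("label values must fit in a byte")
    Image.fromarray(lab.astype(np.uint8), mode="L").save(path)


def read_label_png(path) -> np.ndarray:
    return np.asarray(Image.open(path), dtype=np.int64)


def write_nifti(path, array: np.ndarray, integer: bool = False) -> None:
    import nibabel as nib

    data = np.asarray(array)
    vol = data[:, :, None].astype(np.int16 if integer else np.float32)
    nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))


def read_nifti(path) -> np.ndarray:
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(path)).dataobj)
    return vol[:, :, 0]


def write_manifest(out_dir, manifest: dict) -> Path:
    out_dir = Path(out_dir)
    path = out_dir / MANIFEST_NAME
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return path


def read_manifest(data_dir) -> dict:
    data_dir = Path(data_dir)
    path = data_dir if data_dir.name.endswith(".json") else data_dir / MANIFEST_NAME
    with open(path) as fh:
        return json.load(fh)


def load_split(data_dir, manifest: dict, split: str):
    """Yield (image, label-or-None) pairs for a manifest split."""
    root = Path(data_dir)
    if root.name.endswith(".json"):
        root = root.parent
    out = []
    for entry in manifest["splits"][split]:
        image = read_image_png(root / entry["image"])
        label = read_label_png(root / entry["label"]) if entry.get("label") else None
        out.append((image, label))
    return out
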