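"""Shared fixtures.

The heavyweight end-to-end artifacts (phantom dataset, pre-trained
checkpoint, fine-tuned segmentation model) are built once per session and
shared by the pipeline-level tests, mirroring how the pipeline is actually
run: make-data -> pretrain -> train.
"""

from __future__ import annotations

import numpy as np
import pytest

from bladderseg.io import load_split, read_manifest
from bladderseg.networks import NetConfig, ReconstructionNet, SegmentationNet, transfer_weights
from bladderseg.phantoms import PhantomConfig, generate_dataset
from bladderseg.training import LRPolicy, TrainConfig, pretrain, train_semisupervised

# desk-scale problem sizes for the full pipeline run
E2E = {
    "n_labeled": 60,
    "n_unlabeled": 40,
    "n_test": 20,
    "image_size": 96,
    "base_width": 8,
    "pretrain_epochs": 20,
    "pretrain_lr": 1e-3,
    "train_epochs": 40,
    "lr1": 2e-3,
    "batch_size": 4,
    "seed": 11,
}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def tiny_net_config():
    return NetConfig(base_width=4, latent_dim=4)


@pytest.fixture(scope="session")
def e2e_dataset(tmp_path_factory):
    """60/40/20 phantom dataset at 96x96, fixed seed."""
    out = tmp_path_factory.mktemp("e2e") / "data"
    cfg = PhantomConfig(image_size=E2E["image_size"])
    manifest = generate_dataset(E2E["n_labeled"], E2E["n_unlabeled"], E2E["n_test"],
                                cfg, seed=E2E["seed"], out_dir=out)
    return out, manifest


@pytest.fixture(scope="session")
def e2e_splits(e2e_dataset):
    out, manifest = e2e_dataset
    labeled = load_split(out, manifest, "labeled")
    unlabeled = [im for im, _ in load_split(out, manifest, "unlabeled")]
    test = load_split(out, manifest, "test")
    return labeled, unlabeled, test


@pytest.fixture(scope="session")
def e2e_pretrained(e2e_splits, tmp_path_factory):
    """Reconstruction network pre-trained on all 100 training images."""
    labeled, unlabeled, _ = e2e_splits
    images = [im for im, _ in labeled] + unlabeled
    cfg = TrainConfig(stage="pretrain", optimizer="adam", lr=E2E["pretrain_lr"],
                      epochs=E2E["pretrain_epochs"], batch_size=8, seed=3,
                      crop_size=64)
    net = ReconstructionNet(NetConfig(base_width=E2E["base_width"]), seed=3)
    ckpt = tmp_path_factory.mktemp("ckpt") / "pretrain.npz"
    net, history = pretrain(images, net, cfg, out_ckpt=ckpt)
    return net, history, ckpt


@pytest.fixture(scope="session")
def e2e_model(e2e_splits, e2e_pretrained):
    """Segmentation model fine-tuned from the pre-trained trunk."""
    labeled, unlabeled, _ = e2e_splits
    pre, _, _ = e2e_pretrained
    seg = SegmentationNet(NetConfig(base_width=E2E["base_width"]), seed=4)
    report = transfer_weights(pre, seg)
    policy = LRPolicy(lr1=E2E["lr1"], n_labeled=len(labeled))
    cfg = TrainConfig(stage="segment", optimizer="adamw", lr=E2E["lr1"],
                      epochs=E2E["train_epochs"], batch_size=E2E["batch_size"],
                      seed=5)
    seg, history = train_semisupervised(labeled, unlabeled, seg, cfg, policy,
                                        transfer_report=report)
    return seg, history
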