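"""Encoder-decoder networks with index-preserving unpooling.

Two SegNet-style networks share an identical trunk:

* ``ReconstructionNet`` — the self-supervised reconstruction network: the
  trunk plus a 1x1-conv + sigmoid reconstruction head mapping back to a
  single intensity channel in [0, 1].
* ``SegmentationNet`` — the same trunk plus a 1x1-conv + softmax head over
  the four tissue classes (background, urine, wall, tumor) and a small VAE
  branch attached at the encoder bottleneck, whose evidence terms
  (feature reconstruction MSE + KL to a standard normal) let unlabeled
  images contribute training signal.

The trunk encoder has nine convolution blocks arranged 3-3-3 between three
2x2 max-pooling stages that record per-window argmax indices; the decoder
has four convolution blocks interleaved 1-1-2 with three max-unpooling
stages that place values back at the recorded positions.  Each block is
conv(3x3, same) -> batch norm -> leaky ReLU.  Channel widths grow
(w, 2w, 4w) along the encoder and shrink symmetrically along the decoder.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _nn
from ._nn import ConvBlock, Conv2d, Linear, MaxPool2x2, MaxUnpool2x2, Sigmoid, softmax

__all__ = [
    "NetConfig", "EncoderState", "LatentParams",
    "ReconstructionNet", "SegmentationNet",
    "leaky_relu", "max_pool_with_indices", "max_unpool",
    "reconstruct_forward", "segment_forward", "transfer_weights",
    "save_checkpoint", "load_checkpoint",
]


def leaky_relu(x, a: float = 0.01):
    """f(x) = x for x >= 0, a*x for x < 0 (the 'dead neuron'-free activation)."""
    if a <= 0:
        raise ValueError("leaky ReLU slope must be positive")
    x = np.asarray(x)
    return np.where(x >= 0, x, a * x)


def max_pool_with_indices(features: np.ndarray):
    """2x2/stride-2 max pooling over (N,C,H,W), returning pooled values and
    the per-window argmax index map (0..3, row-major; ties -> first)."""
    return _nn.max_pool2x2(features)


def max_unpool(pooled: np.ndarray, index_map: np.ndarray, out_size) -> np.ndarray:
    """Scatter pooled maxima back to their recorded positions, zero elsewhere."""
    return _nn.max_unpool2x2(pooled, index_map, tuple(out_size))


@dataclass
class NetConfig:
    in_channels: int = 1
    base_width: int = 16
    encoder_blocks: int = 9
    pool_stages: int = 3
    decoder_blocks: int = 4
    upsample_stages: int = 3
    leaky_slope: float = 0.01
    num_classes: int = 4
    latent_dim: int = 16

    def __post_init__(self):
        if self.pool_stages != self.upsample_stages:
            raise ValueError("pool_stages must equal upsample_stages for size symmetry")
        if self.encoder_blocks != 9 or self.decoder_blocks != 4 or self.pool_stages != 3:
            raise ValueError("trunk layout is fixed at 9 encoder blocks / 3 pools / "
                             "4 decoder blocks / 3 unpools")

    @property
    def widths(self) -> tuple[int, int, int]:
        w = self.base_width
        return (w, 2 * w, 4 * w)

    @property
    def divisor(self) -> int:
        return 2 ** self.pool_stages


@dataclass
class EncoderState:
    """Bottleneck features plus everything needed for exact unpooling."""
    bottleneck: np.ndarray
    pool_indices: list[np.ndarray]
    pre_pool_sizes: list[tuple[int, int]]


@dataclass
class LatentParams:
    """Diagonal-Gaussian posterior parameters of the VAE branch."""
    mu: np.ndarray
    log_var: np.ndarray


def _check_input(x: np.ndarray, cfg: NetConfig) -> np.ndarray:
    """Accept (H,W), (N,H,W) or (N,1,H,W); return float32 (N,1,H,W)."""
    x = np.asarray(x, dtype=_nn.F32)
    if x.ndim == 2:
        x = x[None, None]
    elif x.ndim == 3:
        x = x[:, None]
    if x.ndim != 4 or x.shape[1] != cfg.in_channels:
        raise ValueError(f"expected grayscale input, got shape {x.shape}")
    h, w = x.shape[2:]
    d = cfg.divisor
    if h % d or w % d:
        raise ValueError(
            f"input spatial size {h}x{w} must be divisible by 2^{cfg.pool_stages}={d}")
    return x


class _Trunk:
    """Shared encoder/decoder; owns every transferable parameter."""

    def __init__(self, cfg: NetConfig, rng: np.random.Generator):
        w1, w2, w3 = cfg.widths
        s = cfg.leaky_slope
        mk = lambda cin, cout, name: ConvBlock(cin, cout, rng, s, name=name)
        self.enc_stages = [
            [mk(cfg.in_channels, w1, "enc.s1.b1"), mk(w1, w1, "enc.s1.b2"), mk(w1, w1, "enc.s1.b3")],
            [mk(w1, w2, "enc.s2.b1"), mk(w2, w2, "enc.s2.b2"), mk(w2, w2, "enc.s2.b3")],
            [mk(w2, w3, "enc.s3.b1"), mk(w3, w3, "enc.s3.b2"), mk(w3, w3, "enc.s3.b3")],
        ]
        self.pools = [MaxPool2x2() for _ in range(3)]
        self.unpools = [MaxUnpool2x2() for _ in range(3)]
        # decoder interleaving 1-1-2: unpool3->block, unpool2->block, unpool1->2 blocks
        self.dec_blocks = [
            mk(w3, w2, "dec.b1"), mk(w2, w1, "dec.b2"),
            mk(w1, w1, "dec.b3"), mk(w1, w1, "dec.b4"),
        ]

    def parameters(self) -> list[_nn.Param]:
        ps = []
        for stage in self.enc_stages:
            for b in stage:
                ps += b.parameters()
        for b in self.dec_blocks:
            ps += b.parameters()
        return ps

    def bn_layers(self):
        for stage in self.enc_stages:
            for b in stage:
                yield b.bn
        for b in self.dec_blocks:
            yield b.bn

    def encode(self, x: np.ndarray, train: bool) -> EncoderState:
        for stage, pool in zip(self.enc_stages, self.pools):
            for blk in stage:
                x = blk.forward(x, train)
            x = pool.forward(x, train)
        return EncoderState(
            bottleneck=x,
            pool_indices=[p.indices for p in self.pools],
            pre_pool_sizes=[p.in_hw for p in self.pools],
        )

    def decode(self, state: EncoderState, train: bool) -> np.ndarray:
        x = state.bottleneck
        order = [(2, [self.dec_blocks[0]]), (1, [self.dec_blocks[1]]),
                 (0, self.dec_blocks[2:])]
        for stage_i, blocks in order:
            up = self.unpools[stage_i]
            up.indices = state.pool_indices[stage_i]
            up.out_hw = state.pre_pool_sizes[stage_i]
            x = up.forward(x, train)
            for blk in blocks:
                x = blk.forward(x, train)
        return x

    def forward(self, x: np.ndarray, train: bool) -> tuple[np.ndarray, EncoderState]:
        state = self.encode(x, train)
        return self.decode(state, train), state

    def backward(self, d_out: np.ndarray, d_bottleneck: np.ndarray | None = None) -> np.ndarray:
        d = self.dec_blocks[3].backward(d_out)
        d = self.dec_blocks[2].backward(d)
        d = self.unpools[0].backward(d)
        d = self.dec_blocks[1].backward(d)
        d = self.unpools[1].backward(d)
        d = self.dec_blocks[0].backward(d)
        d = self.unpools[2].backward(d)
        if d_bottleneck is not None:
            d = d + d_bottleneck
        for stage, pool in zip(reversed(self.enc_stages), reversed(self.pools)):
            d = pool.backward(d)
            for blk in reversed(stage):
                d = blk.backward(d)
        return d


class _BaseNet:
    config: NetConfig
    trunk: _Trunk

    def trunk_parameters(self) -> list[_nn.Param]:
        return self.trunk.parameters()

    def head_parameters(self) -> list[_nn.Param]:
        raise NotImplementedError

    def parameters(self) -> list[_nn.Param]:
        return self.trunk_parameters() + self.head_parameters()

    def set_eval_noise(self):  # pragma: no cover - placeholder symmetry
        pass


class ReconstructionNet(_BaseNet):
    def __init__(self, config: NetConfig | None = None, seed: int = 0):
        self.config = config or NetConfig()
        rng = np.random.default_rng(seed)
        self.trunk = _Trunk(self.config, rng)
        w1 = self.config.widths[0]
        self.head = Conv2d(w1, 1, 1, rng, self.config.leaky_slope, name="recon_head.conv")
        self.sigmoid = Sigmoid()

    def head_parameters(self) -> list[_nn.Param]:
        return self.head.parameters()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        x = _check_input(x, self.config)
        feat, _ = self.trunk.forward(x, train)
        return self.sigmoid.forward(self.head.forward(feat, train), train)

    def backward(self, d_recon: np.ndarray) -> None:
        d = self.head.backward(self.sigmoid.backward(d_recon))
        self.trunk.backward(d)


class SegmentationNet(_BaseNet):
    def __init__(self, config: NetConfig | None = None, seed: int = 0):
        self.config = config or NetConfig()
        rng = np.random.default_rng(seed)
        self.trunk = _Trunk(self.config, rng)
        cfg = self.config
        w1, _, w3 = cfg.widths
        s = cfg.leaky_slope
        self.head = Conv2d(w1, cfg.num_classes, 1, rng, s, name="seg_head.conv")
        # VAE branch: GAP -> affine to (mu, log var) -> sample -> affine ->
        # spatial tile -> two conv blocks -> 1x1 conv reconstructing the
        # bottleneck feature field
        self.vae_enc = Linear(w3, 2 * cfg.latent_dim, rng, name="vae.enc")
        self.vae_dec_fc = Linear(cfg.latent_dim, w3, rng, name="vae.dec_fc")
        self.vae_block1 = ConvBlock(w3, w3, rng, s, name="vae.block1")
        self.vae_block2 = ConvBlock(w3, w3, rng, s, name="vae.block2")
        self.vae_out = Conv2d(w3, w3, 1, rng, s, name="vae.out")
        self._cache = None

    def head_parameters(self) -> list[_nn.Param]:
        return (self.head.parameters() + self.vae_enc.parameters()
                + self.vae_dec_fc.parameters() + self.vae_block1.parameters()
                + self.vae_block2.parameters() + self.vae_out.parameters())

    def _vae_forward(self, bottleneck: np.ndarray, train: bool,
                     rng: np.random.Generator | None):
        n, c, h, w = bottleneck.shape
        g = bottleneck.mean(axis=(2, 3))
        latpar = self.vae_enc.forward(g, train)
        mu, log_var = latpar[:, : self.config.latent_dim], latpar[:, self.config.latent_dim:]
        log_var = np.clip(log_var, -10.0, 10.0)
        if train and rng is not None:
            eps = rng.standard_normal(mu.shape).astype(_nn.F32)
        else:
            eps = np.zeros_like(mu)  # posterior mean at inference
        z = mu + np.exp(0.5 * log_var) * eps
        d = self.vae_dec_fc.forward(z, train)
        tiled = np.broadcast_to(d[:, :, None, None], (n, c, h, w)).astype(_nn.F32)
        y = self.vae_block1.forward(tiled, train)
        y = self.vae_block2.forward(y, train)
        recon = self.vae_out.forward(y, train)
        if train:
            self._vae_cache = (eps, log_var, (h, w))
        return mu, log_var, recon

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None) -> dict:
        x = _check_input(x, self.config)
        feat, state = self.trunk.forward(x, train)
        logits = self.head.forward(feat, train)
        probs = softmax(logits, axis=1)
        mu, log_var, vae_recon = self._vae_forward(state.bottleneck, train, rng)
        if train:
            self._cache = probs
        return {
            "probs": probs,
            "latent": LatentParams(mu=mu, log_var=log_var),
            "vae_recon": vae_recon,
            # reconstruction target: the bottleneck features, treated as constant
            "vae_target": state.bottleneck.copy(),
        }

    def backward(self, d_probs: np.ndarray, d_recon: np.ndarray,
                 d_mu: np.ndarray, d_log_var: np.ndarray) -> None:
        probs = self._cache
        self._cache = None
        d_logits = _nn.softmax_backward(probs, d_probs, axis=1)
        d_feat = self.head.backward(d_logits)

        eps, log_var, (h, w) = self._vae_cache
        self._vae_cache = None
        dy = self.vae_out.backward(d_recon)
        dy = self.vae_block2.backward(dy)
        dy = self.vae_block1.backward(dy)
        dd = dy.sum(axis=(2, 3))  # adjoint of spatial tiling
        dz = self.vae_dec_fc.backward(dd)
        dmu_total = dz + d_mu
        dlv_total = dz * eps * (0.5 * np.exp(0.5 * log_var)) + d_log_var
        dg = self.vae_enc.backward(
            np.concatenate([dmu_total, dlv_total], axis=1).astype(_nn.F32))
        d_bottleneck = (dg[:, :, None, None] / (h * w)).astype(_nn.F32)
        d_bottleneck = np.broadcast_to(
            d_bottleneck, (dg.shape[0], dg.shape[1], h, w)).copy()
        self.trunk.backward(d_feat, d_bottleneck)


def reconstruct_forward(image: np.ndarray, net: ReconstructionNet) -> np.ndarray:
    """Run an image through the reconstruction network (inference mode)."""
    out = net.forward(image, train=False)
    return out[0, 0] if np.asarray(image).ndim == 2 else out[:, 0]


def segment_forward(image: np.ndarray, net: SegmentationNet):
    """Inference-mode segmentation pass.

    Returns (ProbMap, LatentParams, vae_reconstruction); for a single (H,W)
    input the ProbMap is (num_classes, H, W).
    """
    out = net.forward(image, train=False)
    probs = out["probs"]
    if np.asarray(image).ndim == 2:
        probs = probs[0]
    return probs, out["latent"], out["vae_recon"]


def transfer_weights(pretrained_net: ReconstructionNet, seg_net: SegmentationNet) -> dict:
    """Copy the pre-trained trunk into the segmentation network.

    Every encoder/decoder parameter (and batch-norm running statistic) is
    copied bitwise; the classification head and the VAE branch keep their
    random initialization.  Returns a report mapping each parameter name to
    "transferred" or "random"; running it twice is idempotent.
    """
    src = pretrained_net.trunk_parameters()
    dst = seg_net.trunk_parameters()
    report: dict[str, str] = {}
    for ps, pd in zip(src, dst):
        if ps.data.shape != pd.data.shape:
            raise ValueError(
                f"shape mismatch at {pd.name}: {ps.data.shape} vs {pd.data.shape}")
        pd.data[...] = ps.data
        report[pd.name] = "transferred"
    for bs, bd in zip(pretrained_net.trunk.bn_layers(), seg_net.trunk.bn_layers()):
        bd.running_mean[...] = bs.running_mean
        bd.running_var[...] = bs.running_var
    for p in seg_net.head_parameters():
        report[p.name] = "random"
    return report


def save_checkpoint(path, net: _BaseNet, extra: dict | None = None) -> None:
    arrays = {f"param::{p.name}": p.data for p in net.parameters()}
    for i, bn in enumerate(net.trunk.bn_layers()):
        arrays[f"bnstat::{i}::mean"] = bn.running_mean
        arrays[f"bnstat::{i}::var"] = bn.running_var
    meta = {
        "kind": type(net).__name__,
        "config": asdict(net.config),
        "extra": extra or {},
    }
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[_BaseNet, dict]:
    with np.load(path) as data:
        meta = json.loads(bytes(data["meta"].tobytes()).decode())
        cfg = NetConfig(**meta["config"])
        net: _BaseNet
        if meta["kind"] == "ReconstructionNet":
            net = ReconstructionNet(cfg)
        elif meta["kind"] == "SegmentationNet":
            net = SegmentationNet(cfg)
        else:
            raise ValueError(f"unknown checkpoint kind {meta['kind']!r}")
        for p in net.parameters():
            key = f"param::{p.name}"
            if key not in data:
                raise ValueError(f"checkpoint missing parameter {p.name}")
            if data[key].shape != p.data.shape:
                raise ValueError(f"checkpoint/architecture mismatch at {p.name}")
            p.data[...] = data[key]
        for i, bn in enumerate(net.trunk.bn_layers()):
            bn.running_mean[...] = data[f"bnstat::{i}::mean"]
            bn.running_var[...] = data[f"bnstat::{i}::var"]
    return net, meta["extra"]
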