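"""Executable attention-gated multi-resolution U-Net.

The encoder runs five multi-res blocks with 2x2 max-pooling between levels.
Each decoder stage upsamples bilinearly, halves the channel width with a
multi-res block, and merges the like-shaped encoder skip through an
attention gate: the gate projects the encoder feature x through a bias-free
1x1 conv, channel-means it, squashes with a sigmoid into a per-pixel scalar
a, and outputs the convex combination a*x + (1-a)*x_up.  The merge IS the
skip connection — no concatenation, so channel counts stay consistent with
the audited layer table.  A final full-resolution multi-res block refines
the merged features before the 1x1 output convolution; ``segment`` applies
the sigmoid to yield per-pixel foreground probabilities.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .graph import ModelConfig, ModelGraph, assemble_model
from .nn.layers import DTYPE, sigmoid

__all__ = [
    "AttentionGatedMultiResUNet",
    "build_network",
    "attention_gate_forward",
    "mask_features",
    "multires_forward",
    "segment",
    "extract_features",
    "FEATURE_STAGES",
]

FEATURE_STAGES = tuple([f"encoder-{i}" for i in range(1, 6)]
                       + [f"decoder-{b}" for b in range(5, 0, -1)])


class AttentionGatedMultiResUNet:
    """The network, weight-initialised deterministically from config.seed."""

    def __init__(self, config: ModelConfig):
        if config.upsample_mode != "bilinear":
            raise NotImplementedError(
                "only bilinear upsampling is implemented in the executable "
                "network; the graph audit covers the transpose variant")
        self.config = config
        self.graph: ModelGraph = assemble_model(config)
        f = config.filter_schedule
        rng = np.random.default_rng(config.seed)
        self.enc = []
        prev = config.input_channels
        for i in range(5):
            self.enc.append(nn.MultiResBlock(prev, f[i], rng=rng,
                                             name=f"enc{i + 1}"))
            prev = f[i]
        self.pools = [nn.MaxPool2x2() for _ in range(4)]
        # decoder blocks 5..2 (levels 4..1): upsample, multires, gate
        self.ups = [nn.BilinearUpsample2x() for _ in range(4)]
        self.dec = [nn.MultiResBlock(f[l + 1], f[l], rng=rng,
                                     name=f"dec{l + 2}")
                    for l in (3, 2, 1, 0)]
        self.gates = [nn.AttentionGate(f[l], config.attention_inter_channels,
                                       rng=rng, name=f"gate{l + 1}")
                      for l in (3, 2, 1, 0)]
        self.refine = nn.MultiResBlock(f[0], f[0], rng=rng, name="refine")
        self.out_conv = nn.Conv2d(f[0], 1, 1, rng=rng, name="out")
        # background-prior initialisation: lesions cover a small fraction of
        # a scan, so start the head near sigmoid(-2) ~ 0.12 foreground
        self.out_conv.b.data[:] = -2.0
        self.activations: dict[str, np.ndarray] = {}

    # ------------------------------------------------------------------
    def params(self) -> list[nn.Parameter]:
        ps: list[nn.Parameter] = []
        for m in self.enc:
            ps += m.params()
        for m in self.dec:
            ps += m.params()
        for g in self.gates:
            ps += g.params()
        ps += self.refine.params() + self.out_conv.params()
        return ps

    def n_params(self) -> int:
        return sum(p.data.size for p in self.params())

    def zero_grad(self) -> None:
        for p in self.params():
            p.zero_grad()

    def _bn_layers(self):
        for m in self.enc + self.dec + [self.refine]:
            for sub in (m.sub1, m.sub2, m.sub3):
                yield sub.bn
            if m.short_bn is not None:
                yield m.short_bn

    def get_state(self) -> dict[str, np.ndarray]:
        state = {f"p{i}": p.data.copy() for i, p in enumerate(self.params())}
        for i, bn in enumerate(self._bn_layers()):
            state[f"bn{i}.mean"] = bn.running_mean.copy()
            state[f"bn{i}.var"] = bn.running_var.copy()
        return state

    def set_state(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.params()):
            p.data[...] = state[f"p{i}"]
        for i, bn in enumerate(self._bn_layers()):
            bn.running_mean[...] = state[f"bn{i}.mean"]
            bn.running_var[...] = state[f"bn{i}.var"]

    def save(self, path) -> None:
        np.savez(path, **self.get_state())

    def load(self, path) -> None:
        with np.load(path) as data:
            self.set_state({k: data[k] for k in data.files})

    # ------------------------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Batch NCHW in, logits (N,1,H,W) out."""
        cfg = self.config
        if x.ndim != 4 or x.shape[1] != cfg.input_channels:
            raise ValueError(f"expected (N,{cfg.input_channels},H,W) input, "
                             f"got {x.shape}")
        if x.shape[2] != cfg.input_height or x.shape[3] != cfg.input_width:
            raise ValueError(
                f"input {x.shape[2]}x{x.shape[3]} does not match configured "
                f"{cfg.input_height}x{cfg.input_width}")
        x = np.ascontiguousarray(x, dtype=DTYPE)
        acts = {}
        skips = []
        h = x
        for i in range(5):
            h = self.enc[i].forward(h, train)
            acts[f"encoder-{i + 1}"] = h
            if i < 4:
                skips.append(h)
                h = self.pools[i].forward(h, train)
        for j, b in enumerate(range(5, 1, -1)):   # j=0 -> decoder block 5
            h = self.ups[j].forward(h, train)
            h = self.dec[j].forward(h, train)
            acts[f"decoder-{b}"] = h
            h = self.gates[j].forward(skips[3 - j], h, train)
        h = self.refine.forward(h, train)
        acts["decoder-1"] = h
        logits = self.out_conv.forward(h, train)
        self.activations = acts
        return logits

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.out_conv.backward(dlogits)
        g = self.refine.backward(g)
        skip_grads: list[np.ndarray | None] = [None] * 4
        for j in range(3, -1, -1):                # decoder block 2 first
            dskip, g = self.gates[j].backward(g)
            skip_grads[3 - j] = dskip
            g = self.dec[j].backward(g)
            g = self.ups[j].backward(g)
        for i in range(4, -1, -1):
            g = self.enc[i].backward(g)
            if i > 0:
                g = self.pools[i - 1].backward(g)
                g = g + skip_grads[i - 1]


def build_network(config: ModelConfig) -> AttentionGatedMultiResUNet:
    return AttentionGatedMultiResUNet(config)


# ----------------------------------------------------------------------
# Functional, single-image operations (H x W x C feature-map convention)
# ----------------------------------------------------------------------

def _to_nchw(fmap: np.ndarray) -> np.ndarray:
    if fmap.ndim == 2:
        fmap = fmap[:, :, None]
    return np.ascontiguousarray(
        fmap.transpose(2, 0, 1)[None], dtype=DTYPE)


def _to_hwc(x: np.ndarray) -> np.ndarray:
    return np.ascontiguousarray(x[0].transpose(1, 2, 0))


def attention_gate_forward(x: np.ndarray, x_up: np.ndarray,
                           weights: np.ndarray) -> np.ndarray:
    """Gate two like-shaped HxWxC feature maps.

    ``weights`` is the (inter, C) bias-free 1x1 projection applied to the
    encoder feature ``x``.  Returns a*x + (1-a)*x_up with the per-pixel
    scalar gate a = sigmoid(channel-mean of the projection); every output
    element lies between the corresponding elements of x and x_up.
    """
    if x.shape != x_up.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_up.shape}")
    xb, ub = _to_nchw(x), _to_nchw(x_up)
    weights = np.asarray(weights, dtype=DTYPE)
    if weights.ndim != 2 or weights.shape[1] != xb.shape[1]:
        raise ValueError(
            f"weights must be (inter, {xb.shape[1]}), got {weights.shape}")
    gate = nn.AttentionGate(xb.shape[1], weights.shape[0])
    gate.w.data[...] = weights
    out = gate.forward(xb, ub, train=False)
    out = _to_hwc(out)
    return out if x.ndim == 3 else out[:, :, 0]


def mask_features(features: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Hard binary masking: keep features on the mask support, zero off it,
    broadcast across channels."""
    mask = np.asarray(mask)
    if mask.shape != features.shape[:2]:
        raise ValueError(f"spatial dims mismatch: features "
                         f"{features.shape[:2]} vs mask {mask.shape}")
    if not np.isin(mask, (0, 1)).all():
        raise ValueError("mask must be binary {0,1}")
    m = mask.astype(features.dtype)
    if features.ndim == 3:
        m = m[:, :, None]
    return features * m


def multires_forward(x: np.ndarray, block: nn.MultiResBlock) -> np.ndarray:
    """Run a multi-res block on one HxWxC feature map (same-padding, so
    spatial dims are preserved; channels become ``block.out_ch``)."""
    xb = _to_nchw(x)
    if xb.shape[1] != block.in_ch:
        raise ValueError(
            f"block expects {block.in_ch} channels, got {xb.shape[1]}")
    return _to_hwc(block.forward(xb, train=False))


def segment(image: np.ndarray,
            network: AttentionGatedMultiResUNet) -> np.ndarray:
    """Per-pixel foreground probability map (values strictly in (0,1)) for
    one HxW (or HxWxC) image.

    Probabilities are clamped to [1e-7, 1 - 1e-7] (the same bounds the BCE
    loss uses) so saturated logits never round to exactly 0 or 1.
    """
    logits = network.forward(_to_nchw(image), train=False)
    p = sigmoid(logits)[0, 0].astype(np.float64)
    return np.clip(p, 1e-7, 1.0 - 1e-7)


def extract_features(image: np.ndarray,
                     network: AttentionGatedMultiResUNet,
                     stage: str) -> np.ndarray:
    """Intermediate multi-res activation (HxWxC) at a named stage."""
    if stage not in FEATURE_STAGES:
        raise ValueError(f"unknown stage {stage!r}; valid stages: "
                         f"{', '.join(FEATURE_STAGES)}")
    network.forward(_to_nchw(image), train=False)
    return _to_hwc(network.activations[stage])
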