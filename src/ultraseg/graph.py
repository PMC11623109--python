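"""Declarative model graph for the attention-gated multi-resolution U-Net.

The graph is a pure description — ordered block specs with shapes, channel
counts, and two parameter-count interpretations — so the architecture can be
audited (dimensions, parameter arithmetic, skip wiring) without building or
running the network.  The executable counterpart lives in
:mod:`ultraseg.network`.

Two parameter-count readings coexist:

* ``table_audit`` — each multi-res block is read as a single 3x3 convolution
  with additive bias; each attention gate as one bias-free 1x1 projection to
  the intermediate channel width.  This is the arithmetic under which the
  published per-layer counts of this architecture are reproducible.
* ``canonical`` — the full executable block: three serial 3x3 conv-BN-ReLU
  sub-blocks with equal-thirds filter allocation, concatenated, plus a 1x1
  conv-BN residual branch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

__all__ = [
    "ModelConfig",
    "BlockSpec",
    "ModelGraph",
    "assemble_model",
    "infer_shapes",
    "count_params",
]

DEFAULT_FILTERS = (32, 64, 128, 256, 512)


@dataclass(frozen=True)
class ModelConfig:
    """Configuration of the 5-level encoder / 4-level decoder network.

    ``input_height``/``input_width`` must be divisible by 16 (four exact
    2x2 poolings).  ``filter_schedule`` must be strictly increasing; the
    default doubles at every level.
    """

    input_height: int = 256
    input_width: int = 256
    input_channels: int = 1
    filter_schedule: tuple[int, ...] = DEFAULT_FILTERS
    attention_inter_channels: int = 32
    block_variant: str = "canonical"
    upsample_mode: str = "bilinear"
    seed: int = 0

    def __post_init__(self):
        for label, dim in (("input_height", self.input_height),
                           ("input_width", self.input_width)):
            if dim <= 0 or dim % 16 != 0:
                raise ValueError(
                    f"{label}={dim} is not divisible by 16; the four 2x2 "
                    f"poolings need exact halvings")
        fs = tuple(self.filter_schedule)
        object.__setattr__(self, "filter_schedule", fs)
        if len(fs) != 5:
            raise ValueError("filter_schedule must have 5 entries")
        if any(b <= a for a, b in zip(fs, fs[1:])):
            raise ValueError("filter_schedule must be strictly increasing")
        if self.block_variant not in ("canonical", "table_audit"):
            raise ValueError(f"unknown block_variant {self.block_variant!r}")
        if self.upsample_mode not in ("bilinear", "transpose"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")

    def with_size(self, height: int, width: int) -> "ModelConfig":
        return replace(self, input_height=height, input_width=width)


@dataclass(frozen=True)
class BlockSpec:
    """One row of the architecture table."""

    block: str          # e.g. "Encoder Block 2"
    label: str          # machine label, e.g. "encoder-2.multires"
    stage: int          # 1..5 resolution level
    kind: str           # multires | attention_gate | maxpool | upsample | output_conv
    name: str           # printed row name
    filters: int | None
    in_channels: int         # channels entering the executable block
    audit_in_channels: int   # channels under the single-3x3-conv reading
    out_channels: int
    out_height: int
    out_width: int
    inter_channels: int = 32
    upsample_mode: str = "bilinear"


@dataclass(frozen=True)
class ModelGraph:
    config: ModelConfig
    blocks: tuple[BlockSpec, ...]
    # encoder stage -> label of the decoder block consuming its skip
    skips: dict[int, str] = field(default_factory=dict)

    def block(self, label: str) -> BlockSpec:
        for b in self.blocks:
            if b.label == label:
                return b
        raise KeyError(label)

    def to_table(self, interpretation: str | None = None) -> list[dict]:
        """Rows with columns Block, Name, Filters, Dimensions, Params,
        Operation — a plain-text-friendly mirror of the layer table."""
        interp = interpretation or self.config.block_variant
        op_names = {"multires": "Convolution", "attention_gate": "Attention",
                    "maxpool": "Pooling", "upsample": "Up-sampling",
                    "output_conv": "Convolution"}
        rows = []
        for b in self.blocks:
            rows.append({
                "Block": b.block,
                "Name": b.name,
                "Filters": b.filters if b.filters is not None else "-",
                "Dimensions": f"{b.out_height} x {b.out_width} x {b.out_channels}",
                "Params": count_params(b, interp),
                "Operation": op_names[b.kind],
            })
        return rows

    def to_json(self, interpretation: str | None = None) -> str:
        return json.dumps(self.to_table(interpretation), indent=2)

    def format_table(self, interpretation: str | None = None) -> str:
        rows = self.to_table(interpretation)
        cols = ["Block", "Name", "Filters", "Dimensions", "Params", "Operation"]
        widths = {c: max(len(c), *(len(str(r[c])) for r in rows)) for c in cols}
        lines = ["  ".join(c.ljust(widths[c]) for c in cols)]
        prev_block = None
        for r in rows:
            shown = dict(r)
            if shown["Block"] == prev_block:
                shown["Block"] = ""
            prev_block = r["Block"]
            lines.append("  ".join(str(shown[c]).ljust(widths[c]) for c in cols))
        return "\n".join(lines)


def _multires_canonical_params(in_ch: int, out_ch: int) -> int:
    f1 = out_ch // 3
    f2 = out_ch // 3
    f3 = out_ch - f1 - f2
    n = 0
    for ci, co in ((in_ch, f1), (f1, f2), (f2, f3)):
        n += 9 * ci * co + co      # 3x3 conv + bias
        n += 2 * co                # batch-norm gamma/beta
    n += in_ch * out_ch + out_ch   # 1x1 residual conv + bias
    n += 2 * out_ch                # residual batch-norm
    return n


def count_params(block: BlockSpec, interpretation: str) -> int:
    """Learnable-parameter count of one block under an interpretation.

    ``table_audit``: multi-res = one 3x3 conv ``audit_in_channels ->
    out_channels`` with bias; attention gate = bias-free 1x1 conv to
    ``inter_channels``; pooling and bilinear upsampling are free.
    ``canonical``: the full executable block arithmetic.
    """
    if interpretation not in ("table_audit", "canonical"):
        raise ValueError(f"unknown interpretation {interpretation!r}")
    if block.kind == "multires":
        if interpretation == "table_audit":
            return (9 * block.audit_in_channels + 1) * block.out_channels
        return _multires_canonical_params(block.in_channels,
                                          block.out_channels)
    if block.kind == "attention_gate":
        return block.in_channels * block.inter_channels
    if block.kind == "maxpool":
        return 0
    if block.kind == "upsample":
        if interpretation == "canonical" and block.upsample_mode == "transpose":
            return 4 * block.in_channels * block.out_channels + block.out_channels
        return 0
    if block.kind == "output_conv":
        return block.in_channels * block.out_channels + block.out_channels
    raise ValueError(f"unknown block kind {block.kind!r}")


def assemble_model(config: ModelConfig) -> ModelGraph:
    """Build the declarative graph: 5 encoder stages (multi-res + attention
    gate, max-pool after stages 1-4), 4 upsampling decoder stages, a
    full-resolution refinement stage, and a 1x1 sigmoid output conv.

    The decoder ``audit_in_channels`` follow the channel pairs implied by
    the published per-row counts under the single-3x3-conv reading; they are
    row data, not derivable from a single channel-flow rule.
    """
    f = config.filter_schedule
    h, w = config.input_height, config.input_width
    ic = config.attention_inter_channels
    blocks: list[BlockSpec] = []
    skips: dict[int, str] = {}

    def dims(level: int) -> tuple[int, int]:
        return h >> (level - 1), w >> (level - 1)

    # --- encoder ---
    prev_ch = config.input_channels
    for i in range(1, 6):
        hi, wi = dims(i)
        blk = f"Encoder Block {i}"
        blocks.append(BlockSpec(blk, f"encoder-{i}.multires", i, "multires",
                                "Multi-Res Block", f[i - 1], prev_ch,
                                f[i - 2] if i > 1 else f[0], f[i - 1], hi, wi))
        blocks.append(BlockSpec(blk, f"encoder-{i}.gate", i, "attention_gate",
                                "Attention Gate", None, f[i - 1], f[i - 1],
                                f[i - 1], hi, wi, inter_channels=ic))
        if i < 5:
            blocks.append(BlockSpec(blk, f"encoder-{i}.pool", i, "maxpool",
                                    "Maxpool 2 x 2", None, f[i - 1], f[i - 1],
                                    f[i - 1], hi // 2, wi // 2))
            skips[i] = f"decoder-{i + 1}"
        prev_ch = f[i - 1]
    # --- decoder blocks 5..2: upsample, multi-res (channel halving), gate ---
    for b in range(5, 1, -1):
        level = b - 1                     # resolution level of this block
        hb, wb = dims(level)
        blk = f"Decoder Block {b}"
        blocks.append(BlockSpec(blk, f"decoder-{b}.upsample", level,
                                "upsample", "UpSample 2 x 2", None, f[b - 1],
                                f[b - 1], f[b - 1], hb, wb,
                                upsample_mode=config.upsample_mode))
        blocks.append(BlockSpec(blk, f"decoder-{b}.multires", level,
                                "multires", "Multi-Res Block", f[b - 1],
                                f[b - 1], f[3], f[b - 2], hb, wb))
        blocks.append(BlockSpec(blk, f"decoder-{b}.gate", level,
                                "attention_gate", "Attention Gate", None,
                                f[b - 2], f[b - 2], f[b - 2], hb, wb,
                                inter_channels=ic))
    # --- decoder block 1: full-resolution refinement ---
    blocks.append(BlockSpec("Decoder Block 1", "decoder-1.multires", 1,
                            "multires", "Multi-Res Block", f[0], f[0], f[2],
                            f[0], h, w))
    blocks.append(BlockSpec("Decoder Block 1", "decoder-1.gate", 1,
                            "attention_gate", "Attention Gate", None, f[0],
                            f[0], f[0], h, w, inter_channels=ic))
    blocks.append(BlockSpec("Output", "output", 1, "output_conv", "Conv 1 x 1",
                            1, f[0], f[0], 1, h, w))
    return ModelGraph(config=config, blocks=tuple(blocks), skips=skips)


# Reference per-row parameter counts of this architecture's layer table for
# the default 256x256x1 configuration.  Under the table-audit reading the
# arithmetic reproduces the rows listed in AUDITED_LABELS exactly; the three
# rows in UNRECONCILED_LABELS do not follow from any consistent conv
# arithmetic (encoder-1 fits a 32->32 conv+BN rather than a 1-channel input;
# encoder-5 appears to have lost a leading digit; the output row fits a
# 64->1 conv though its input is 32 channels) and are kept for diffing only.
REFERENCE_PARAMS = {
    "encoder-1.multires": 9_280,
    "encoder-1.gate": 1_024,
    "encoder-2.multires": 18_496,
    "encoder-2.gate": 2_048,
    "encoder-3.multires": 73_856,
    "encoder-3.gate": 4_096,
    "encoder-4.multires": 295_168,
    "encoder-4.gate": 8_192,
    "encoder-5.multires": 180_160,
    "encoder-5.gate": 16_384,
    "decoder-5.multires": 590_080,
    "decoder-5.gate": 8_192,
    "decoder-4.multires": 295_040,
    "decoder-4.gate": 4_096,
    "decoder-3.multires": 147_520,
    "decoder-3.gate": 2_048,
    "decoder-2.multires": 73_760,
    "decoder-2.gate": 1_024,
    "decoder-1.multires": 36_896,
    "decoder-1.gate": 1_024,
    "output": 65,
}

AUDITED_LABELS = (
    "encoder-1.gate", "encoder-2.gate", "encoder-3.gate", "encoder-4.gate",
    "encoder-5.gate",
    "encoder-2.multires", "encoder-3.multires", "encoder-4.multires",
    "decoder-5.multires", "decoder-4.multires",
    "decoder-3.multires", "decoder-2.multires", "decoder-1.multires",
    "decoder-5.gate", "decoder-4.gate", "decoder-3.gate", "decoder-2.gate",
    "decoder-1.gate",
)

UNRECONCILED_LABELS = ("encoder-1.multires", "encoder-5.multires", "output")


def infer_shapes(graph: ModelGraph) -> list[tuple[str, int, int, int]]:
    """One (label, height, width, channels) record per block, in table
    order; the final record is the full-resolution single-channel output."""
    return [(b.label, b.out_height, b.out_width, b.out_channels)
            for b in graph.blocks]
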