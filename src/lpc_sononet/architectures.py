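"""Network definitions: LPC-SonoNet, the SonoNet64 baseline, and analysis.

A network is described declaratively by an :class:`ArchSpec` — an ordered
list of block descriptors plus an adaptation-head descriptor — from which
both a runnable model (:func:`instantiate`) and a closed-form trainable
parameter count (:func:`count_parameters`) derive. Keeping the two routes
separate lets tests check one against the other by brute-force enumeration.

Both networks are fully convolutional: a VGG-style ladder of bias-free
convolutions with batch normalization for SonoNet64, and four light pyramid
convolution (LPC) blocks for LPC-SonoNet, followed by a shared adaptation
head (1x1 convolutions down to K class channels, then a global spatial max
pool). The global max pool makes the class score the best response anywhere
in the image, so inputs of any sufficiently large size are accepted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np

from . import nn

__all__ = [
    "LPCBlockConfig",
    "ConvStackConfig",
    "HeadConfig",
    "ArchSpec",
    "ParamReport",
    "ChannelLoadReport",
    "build_sononet64",
    "build_lpc_sononet",
    "build_lpc_block",
    "count_parameters",
    "channel_load",
    "instantiate",
    "Network",
    "min_input_size",
]


class InvalidConfiguration(ValueError):
    """Raised when an architecture description violates its invariants."""


@dataclass(frozen=True)
class LPCBlockConfig:
    """Channel triple of one pyramid block.

    ``in_ch`` feeds the first 3x3 convolution; ``hidden_ch`` is the width of
    both 3x3 pyramid convolutions; the 1x1 fusion convolution maps the
    concatenation of the input and both pyramid maps (``in_ch + 2*hidden_ch``
    channels, three receptive-field scales) to ``out_ch``.
    """

    in_ch: int
    hidden_ch: int
    out_ch: int

    def __post_init__(self):
        if min(self.in_ch, self.hidden_ch, self.out_ch) < 1:
            raise InvalidConfiguration(
                "all channel counts of an LPC block must be >= 1")

    @property
    def concat_width(self) -> int:
        return self.in_ch + 2 * self.hidden_ch


@dataclass(frozen=True)
class ConvStackConfig:
    """A plain stack of 3x3 conv+norm+rectifier layers (VGG-style block)."""

    in_ch: int
    out_channels: tuple  # output width of each conv in the stack

    def __post_init__(self):
        if self.in_ch < 1 or not self.out_channels or \
                min(self.out_channels) < 1:
            raise InvalidConfiguration("conv stack needs positive widths")

    @property
    def out_ch(self) -> int:
        return self.out_channels[-1]


@dataclass(frozen=True)
class HeadConfig:
    """Adaptation head: 1x1 conv in->mid (norm+rectifier), 1x1 conv mid->K
    (norm), global spatial max pool."""

    in_ch: int
    mid_ch: int
    num_classes: int


@dataclass(frozen=True)
class ArchSpec:
    name: str
    input_channels: int
    num_classes: int
    blocks: tuple  # LPCBlockConfig or ConvStackConfig, in order
    pool_after: tuple  # bool per block
    head: HeadConfig

    def __post_init__(self):
        if self.num_classes < 2:
            raise InvalidConfiguration("need at least 2 classes")
        if len(self.blocks) != len(self.pool_after):
            raise InvalidConfiguration("pool_after must match blocks")
        prev = self.input_channels
        for b in self.blocks:
            if b.in_ch != prev:
                raise InvalidConfiguration(
                    f"block input width {b.in_ch} != previous output {prev}")
            prev = b.out_ch
        if self.head.in_ch != prev:
            raise InvalidConfiguration(
                "head input width must equal last block output")
        if self.head.num_classes != self.num_classes:
            raise InvalidConfiguration("head class count mismatch")

    @property
    def num_pools(self) -> int:
        return sum(bool(p) for p in self.pool_after)

    # --- serialization (round-trip stable) --------------------------------
    def to_dict(self) -> dict:
        blocks = []
        for b, p in zip(self.blocks, self.pool_after):
            if isinstance(b, LPCBlockConfig):
                blocks.append({"kind": "lpc", "in_ch": b.in_ch,
                               "hidden_ch": b.hidden_ch, "out_ch": b.out_ch,
                               "pool_after": bool(p)})
            else:
                blocks.append({"kind": "conv_stack", "in_ch": b.in_ch,
                               "out_channels": list(b.out_channels),
                               "pool_after": bool(p)})
        return {"name": self.name, "input_channels": self.input_channels,
                "num_classes": self.num_classes, "blocks": blocks,
                "head": {"in_ch": self.head.in_ch,
                         "mid_ch": self.head.mid_ch,
                         "num_classes": self.head.num_classes}}

    @staticmethod
    def from_dict(d: dict) -> "ArchSpec":
        blocks, pools = [], []
        for b in d["blocks"]:
            pools.append(bool(b["pool_after"]))
            if b["kind"] == "lpc":
                blocks.append(LPCBlockConfig(b["in_ch"], b["hidden_ch"],
                                             b["out_ch"]))
            elif b["kind"] == "conv_stack":
                blocks.append(ConvStackConfig(b["in_ch"],
                                              tuple(b["out_channels"])))
            else:
                raise InvalidConfiguration(f"unknown block kind {b['kind']!r}")
        h = d["head"]
        return ArchSpec(d["name"], d["input_channels"], d["num_classes"],
                        tuple(blocks), tuple(pools),
                        HeadConfig(h["in_ch"], h["mid_ch"], h["num_classes"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @staticmethod
    def from_json(s: str) -> "ArchSpec":
        return ArchSpec.from_dict(json.loads(s))


@dataclass
class ParamReport:
    per_layer: list  # (layer id, trainable parameter count)
    total: int
    total_millions: float


@dataclass
class ChannelLoadReport:
    """Diagnostic only: input-channel count seen by each convolution."""

    per_layer_channels: list
    mean_channels: float


# ---------------------------------------------------------------------------
# builders

_SONONET64_LADDER = ((64, 64), (128, 128), (256, 256, 256),
                     (512, 512, 512), (512, 512, 512))
_LPC_OUT_LADDER = (64, 256, 512, 512)


def build_sononet64(num_classes: int, input_channels: int = 1) -> ArchSpec:
    """The five-block VGG-style SonoNet64 baseline.

    Conv ladder 64,64 | 128,128 | 256x3 | 512x3 | 512x3 (all 3x3, bias-free,
    batch norm + rectifier), 2x2 max pool after blocks 1-4, adaptation head
    512 -> 256 -> K.
    """
    if num_classes < 2:
        raise InvalidConfiguration("need at least 2 classes")
    blocks, prev = [], input_channels
    for widths in _SONONET64_LADDER:
        blocks.append(ConvStackConfig(prev, tuple(widths)))
        prev = widths[-1]
    return ArchSpec(name="sononet64", input_channels=input_channels,
                    num_classes=num_classes, blocks=tuple(blocks),
                    pool_after=(True, True, True, True, False),
                    head=HeadConfig(prev, 256, num_classes))


def build_lpc_sononet(num_classes: int, input_channels: int = 1) -> ArchSpec:
    """The four-block LPC-SonoNet.

    One block fewer than SonoNet64 (output ladder 64, 256, 512, 512), each
    block a pyramid block with hidden width half the output width, 2x2 max
    pool after blocks 1-3, and the same 512 -> 256 -> K adaptation head.
    """
    if num_classes < 2:
        raise InvalidConfiguration("need at least 2 classes")
    blocks, prev = [], input_channels
    for out in _LPC_OUT_LADDER:
        blocks.append(LPCBlockConfig(prev, out // 2, out))
        prev = out
    return ArchSpec(name="lpc_sononet", input_channels=input_channels,
                    num_classes=num_classes, blocks=tuple(blocks),
                    pool_after=(True, True, True, False),
                    head=HeadConfig(prev, 256, num_classes))


def build_lpc_block(cfg: LPCBlockConfig,
                    rng: np.random.Generator | None = None) -> nn.LPCBlock:
    """Instantiate a single runnable LPC block (mainly for tests/analysis)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    return nn.LPCBlock("lpc", cfg.in_ch, cfg.hidden_ch, cfg.out_ch, rng)


# ---------------------------------------------------------------------------
# closed-form parameter accounting

def _round_half_up_millions(total: int) -> float:
    return float(Decimal(total).scaleb(-6).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


def _conv_params(in_ch: int, out_ch: int, kernel: int) -> int:
    return kernel * kernel * in_ch * out_ch  # bias-free


def _iter_layers(spec: ArchSpec):
    """Yield (layer id, kind, in_ch, out_ch, kernel) for every learnable
    conv, with its batch norm listed right after it."""
    for bi, block in enumerate(spec.blocks, start=1):
        if isinstance(block, LPCBlockConfig):
            base = f"block{bi}"
            yield (f"{base}.conv_a.conv", "conv", block.in_ch,
                   block.hidden_ch, 3)
            yield (f"{base}.conv_a.bn", "bn", block.hidden_ch, None, None)
            yield (f"{base}.conv_b.conv", "conv", block.hidden_ch,
                   block.hidden_ch, 3)
            yield (f"{base}.conv_b.bn", "bn", block.hidden_ch, None, None)
            yield (f"{base}.fuse.conv", "conv", block.concat_width,
                   block.out_ch, 1)
            yield (f"{base}.fuse.bn", "bn", block.out_ch, None, None)
        else:
            prev = block.in_ch
            for ci, out in enumerate(block.out_channels, start=1):
                yield (f"block{bi}.conv{ci}.conv", "conv", prev, out, 3)
                yield (f"block{bi}.conv{ci}.bn", "bn", out, None, None)
                prev = out
    h = spec.head
    yield ("head.reduce.conv", "conv", h.in_ch, h.mid_ch, 1)
    yield ("head.reduce.bn", "bn", h.mid_ch, None, None)
    yield ("head.classify.conv", "conv", h.mid_ch, h.num_classes, 1)
    yield ("head.classify.bn", "bn", h.num_classes, None, None)


def count_parameters(spec: ArchSpec) -> ParamReport:
    """Closed-form trainable parameter count.

    3x3 conv contributes 9*in*out, 1x1 conv in*out (no biases), batch norm
    2*channels (scale and shift); pooling and rectifiers contribute nothing.
    ``total_millions`` rounds half-up to one decimal, the precision model
    sizes are conventionally quoted at.
    """
    per_layer = []
    for lid, kind, a, b, k in _iter_layers(spec):
        if kind == "conv":
            per_layer.append((lid, _conv_params(a, b, k)))
        else:
            per_layer.append((lid, 2 * a))
    total = sum(c for _, c in per_layer)
    return ParamReport(per_layer=per_layer, total=total,
                       total_millions=_round_half_up_millions(total))


def channel_load(spec: ArchSpec) -> ChannelLoadReport:
    """Mean number of input channels over all convolutions (head included).

    A rough proxy for how wide the tensors each convolution must process
    are. Diagnostic only: there is no canonical definition of this summary,
    and different conventions shift it by tens of channels.
    """
    chans = [a for _, kind, a, _, _ in _iter_layers(spec) if kind == "conv"]
    return ChannelLoadReport(per_layer_channels=chans,
                             mean_channels=float(np.mean(chans)))


# ---------------------------------------------------------------------------
# instantiation

class Network(nn.Model):
    """A runnable model carrying its spec; validates minimum input size."""

    def __init__(self, spec: ArchSpec, stages: list):
        super().__init__(stages)
        self.spec = spec
        self.min_size = 2 ** spec.num_pools

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.ndim != 4 or x.shape[1] != self.spec.input_channels:
            raise ValueError(
                f"expected input of shape (N, {self.spec.input_channels}, "
                f"H, W), got {x.shape}")
        n, _, h, w = x.shape
        if h < self.min_size or w < self.min_size:
            raise ValueError(
                f"input {h}x{w} too small: {self.spec.name} applies "
                f"{self.spec.num_pools} 2x2 poolings, so both spatial "
                f"dimensions must be at least {self.min_size}")
        return super().forward(x.astype(np.float32), train)


def min_input_size(spec: ArchSpec) -> int:
    """Smallest spatial extent that survives all pooling stages."""
    return 2 ** spec.num_pools


def instantiate(spec: ArchSpec, seed: int = 0) -> Network:
    """Build a runnable, seeded network from a spec.

    Initialization is fan-in-scaled normal; two calls with the same spec and
    seed produce bit-identical parameters.
    """
    rng = np.random.default_rng(seed)
    stages = []
    for bi, (block, pool) in enumerate(zip(spec.blocks, spec.pool_after),
                                       start=1):
        name = f"block{bi}"
        if isinstance(block, LPCBlockConfig):
            stages.append((name, nn.LPCBlock(name, block.in_ch,
                                             block.hidden_ch, block.out_ch,
                                             rng)))
        else:
            stages.append((name, _ConvStack(name, block, rng)))
        if pool:
            stages.append((f"pool{bi}", nn.MaxPool2d()))
    stages.append(("head", nn.AdaptationHead("head", spec.head.in_ch,
                                             spec.head.mid_ch,
                                             spec.head.num_classes, rng)))
    return Network(spec, stages)


class _ConvStack(nn.Layer):
    def __init__(self, name: str, cfg: ConvStackConfig,
                 rng: np.random.Generator):
        self.layers = []
        prev = cfg.in_ch
        for ci, out in enumerate(cfg.out_channels, start=1):
            self.layers.append(nn.ConvBNReLU(f"{name}.conv{ci}", prev, out,
                                             3, rng))
            prev = out

    def params(self):
        out = []
        for l in self.layers:
            out.extend(l.params())
        return out

    def forward(self, x, train=False):
        for l in self.layers:
            x = l.forward(x, train)
        return x

    def backward(self, dy):
        for l in reversed(self.layers):
            dy = l.backward(dy)
        return dy
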