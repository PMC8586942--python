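"""Explicit layer graphs for the five tiny-object segmentation networks.

The five architectures (``unet``, ``half_unet``, ``multiresunet``,
``half_multiresunet``, ``quarter_multiresunet``) are encoder–decoder
networks for binary segmentation of very small foreground objects
(3–10 px particles on a textured background).  Each model is represented
as an explicit directed acyclic graph of primitive nodes — ``conv``,
``maxpool2``, ``upsample2``, ``concat``, ``add``, ``relu`` — rather than
as opaque framework layers, so that parameter counting, FLOP accounting,
receptive-field analysis and weight-histogram inspection can all walk
the same structure the forward pass executes.

Conventions
-----------
* All convolutions use "same" zero padding at stride 1, so the output
  mask has the full input resolution.
* Downsampling is 2x2 max pooling; upsampling is 2x nearest-neighbour
  interpolation (no transposed convolutions anywhere).
* Each encoder/decoder stage applies two stacked convolutions (plain
  U-net family) or a MultiRes block, with a single ReLU at the end of
  the stage; the first convolution of a pair is linear.
* Skip connections concatenate the encoder output (first operand) with
  the upsampled decoder tensor (second operand).  In the MultiRes family
  the encoder output passes through a residual path first.
* The output head is a 1x1 convolution to one channel with a sigmoid.

MultiRes block
--------------
``MRB(X)`` chains three 3x3 ReLU convolutions with output widths
``(out/6, out/3, out/2)``, concatenates the three branch outputs and
adds the block input through a residual shortcut.  When the input and
output widths agree the shortcut is the identity (the pure residual
form); when a stage changes width the shortcut is a 1x1 projection
convolution, as in the original MultiResUNet.

Residual path
-------------
``RP(X)`` repeats, exactly four times, the basic block
``f(X) = relu(conv1(X)) + relu(conv3(X))``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

ARCH_NAMES = (
    "unet",
    "half_unet",
    "multiresunet",
    "half_multiresunet",
    "quarter_multiresunet",
)

ACTIVATIONS = ("linear", "relu", "sigmoid")


class GraphError(ValueError):
    """Raised for inconsistent model specifications."""


@dataclass
class ConvSpec:
    """A single convolution: ``y = act(W * x + b)`` with same padding."""

    kernel_size: int
    stride: int
    in_channels: int
    out_channels: int
    activation: str = "linear"
    kernel: np.ndarray | None = None  # (k, k, cin, cout)
    bias: np.ndarray | None = None  # (cout,)

    def __post_init__(self) -> None:
        if self.kernel_size < 1 or self.stride < 1:
            raise GraphError("kernel size and stride must be >= 1")
        if self.in_channels < 1 or self.out_channels < 1:
            raise GraphError("channel counts must be positive")
        if self.activation not in ACTIVATIONS:
            raise GraphError(f"unknown activation {self.activation!r}")
        if self.kernel is not None:
            expect = (self.kernel_size, self.kernel_size,
                      self.in_channels, self.out_channels)
            if tuple(self.kernel.shape) != expect:
                raise GraphError(
                    f"kernel shape {self.kernel.shape} != {expect}")
        if self.bias is not None and self.bias.shape != (self.out_channels,):
            raise GraphError("bias shape inconsistent with out_channels")

    @property
    def n_parameters(self) -> int:
        k = self.kernel_size
        return k * k * self.in_channels * self.out_channels + self.out_channels


@dataclass
class Node:
    """One vertex of the layer graph."""

    id: str
    op: str  # input | conv | maxpool2 | upsample2 | concat | add | relu
    inputs: tuple[str, ...] = ()
    conv: ConvSpec | None = None
    stage: int | None = None  # stage index in the paper's 0..2d numbering
    kind: str | None = None  # feature | skip | output


@dataclass
class ModelSpec:
    """A validated architecture graph plus input/output contracts."""

    name: str
    nodes: list[Node]
    input_shape: tuple[int, int, int]  # (H, W, C)
    output_shape: tuple[int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        self.validate()
        h, w, _ = self.input_shape
        self.output_shape = (h, w, 1)

    # -- structure ---------------------------------------------------------
    def node(self, node_id: str) -> Node:
        try:
            return self._index[node_id]
        except AttributeError:
            self._index = {n.id: n for n in self.nodes}
            return self._index[node_id]

    def conv_nodes(self) -> list[Node]:
        return [n for n in self.nodes if n.op == "conv"]

    @property
    def output_id(self) -> str:
        return self.nodes[-1].id

    def validate(self) -> None:
        seen: set[str] = set()
        for node in self.nodes:
            if node.id in seen:
                raise GraphError(f"duplicate node id {node.id!r}")
            for src in node.inputs:
                if src not in seen:
                    raise GraphError(
                        f"node {node.id!r} consumes {src!r} before its "
                        "definition (graph must be topologically ordered "
                        "and acyclic)")
            if node.op == "conv" and node.conv is None:
                raise GraphError(f"conv node {node.id!r} lacks a ConvSpec")
            seen.add(node.id)
        last = self.nodes[-1]
        if not (last.op == "conv" and last.conv.out_channels == 1
                and last.conv.activation == "sigmoid"):
            raise GraphError(
                "final node must be a sigmoid-activated 1-channel conv")
        self.infer_shapes()  # raises on any shape inconsistency

    def infer_shapes(self) -> dict[str, tuple[int, int, int]]:
        """Propagate (H, W, C) through the graph, checking consistency."""
        shapes: dict[str, tuple[int, int, int]] = {}
        for node in self.nodes:
            ins = [shapes[i] for i in node.inputs]
            if node.op == "input":
                shapes[node.id] = self.input_shape
            elif node.op == "conv":
                h, w, c = ins[0]
                spec = node.conv
                if c != spec.in_channels:
                    raise GraphError(
                        f"{node.id}: input has {c} channels, conv expects "
                        f"{spec.in_channels}")
                s = spec.stride
                shapes[node.id] = (h // s, w // s, spec.out_channels)
            elif node.op == "maxpool2":
                h, w, c = ins[0]
                if h % 2 or w % 2:
                    raise GraphError(f"{node.id}: odd spatial size {h}x{w}")
                shapes[node.id] = (h // 2, w // 2, c)
            elif node.op == "upsample2":
                h, w, c = ins[0]
                shapes[node.id] = (h * 2, w * 2, c)
            elif node.op == "concat":
                hw = {(h, w) for h, w, _ in ins}
                if len(hw) != 1:
                    raise GraphError(
                        f"{node.id}: concat operands disagree spatially {hw}")
                (h, w), = hw
                shapes[node.id] = (h, w, sum(c for _, _, c in ins))
            elif node.op == "add":
                if len(set(ins)) != 1:
                    raise GraphError(
                        f"{node.id}: add operands must match exactly, "
                        f"got {ins}")
                shapes[node.id] = ins[0]
            elif node.op == "relu":
                shapes[node.id] = ins[0]
            else:
                raise GraphError(f"unknown op {node.op!r}")
        out_h, out_w, _ = shapes[self.nodes[-1].id]
        if (out_h, out_w) != self.input_shape[:2]:
            raise GraphError("output spatial size differs from input")
        return shapes

    # -- weights -----------------------------------------------------------
    def initialize(self, rng: np.random.Generator | int | None = 0) -> "ModelSpec":
        """Glorot-uniform kernels, zero biases (in place); returns self."""
        rng = np.random.default_rng(rng)
        for node in self.conv_nodes():
            spec = node.conv
            k = spec.kernel_size
            fan_in = k * k * spec.in_channels
            fan_out = k * k * spec.out_channels
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            spec.kernel = rng.uniform(
                -limit, limit,
                (k, k, spec.in_channels, spec.out_channels),
            ).astype(np.float32)
            spec.bias = np.zeros(spec.out_channels, dtype=np.float32)
        return self

    def parameters(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Mapping node id -> (kernel, bias) for all conv nodes."""
        out = {}
        for node in self.conv_nodes():
            if node.conv.kernel is None:
                raise GraphError(f"{node.id}: weights not initialized")
            out[node.id] = (node.conv.kernel, node.conv.bias)
        return out


# ---------------------------------------------------------------------------
# primitive tensor ops (NHWC layout, float32)
# ---------------------------------------------------------------------------

def conv2d_same(x: np.ndarray, kernel: np.ndarray, bias: np.ndarray,
                stride: int = 1) -> np.ndarray:
    """Same-padded 2-D convolution of an NHWC batch.

    Evaluated as one matrix product per kernel tap on the contiguous
    input, accumulated with spatial shifts — equivalent to im2col but
    without materializing the column matrix.  Only stride 1 occurs in
    these architectures (resolution changes use pooling/upsampling);
    larger strides subsample the stride-1 result.
    """
    k = kernel.shape[0]
    cin, cout = kernel.shape[2], kernel.shape[3]
    n, h, w, _ = x.shape
    if k == 1:
        out = x.reshape(n * h * w, cin) @ kernel.reshape(cin, cout)
        out += bias
        out = out.reshape(n, h, w, cout)
        return out[:, ::stride, ::stride] if stride > 1 else out
    pad = (k - 1) // 2
    xm = x.reshape(n * h * w, cin)
    # One matrix product per kernel tap on the contiguous input,
    # accumulated into a padded output: contributions that would need a
    # zero-padded input land in the discarded border instead.  All
    # strided writes have w*cout-long contiguous runs.
    outp = np.zeros((n, h + 2 * pad, w + 2 * pad, cout), dtype=np.float32)
    for u in range(k):
        du = u - pad
        for v in range(k):
            dv = v - pad
            t = (xm @ kernel[u, v]).reshape(n, h, w, cout)
            outp[:, pad - du:pad - du + h, pad - dv:pad - dv + w] += t
    out = outp[:, pad:pad + h, pad:pad + w]
    out += bias
    return out[:, ::stride, ::stride] if stride > 1 else out


def maxpool2(x: np.ndarray) -> np.ndarray:
    n, h, w, c = x.shape
    return x.reshape(n, h // 2, 2, w // 2, 2, c).max(axis=(2, 4))


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=1).repeat(2, axis=2)


def apply_activation(x: np.ndarray, activation: str) -> np.ndarray:
    if activation == "linear":
        return x
    if activation == "relu":
        return np.maximum(x, 0.0)
    if activation == "sigmoid":
        # numerically stable logistic
        out = np.empty_like(x)
        pos = x >= 0
        out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out[~pos] = ex / (1.0 + ex)
        return out
    raise GraphError(f"unknown activation {activation!r}")


def evaluate(model: ModelSpec, x: np.ndarray,
             keep: Iterable[str] | None = None) -> dict[str, np.ndarray]:
    """Run the graph on an NHWC batch; return activations by node id.

    Intermediate tensors are discarded as soon as no later node consumes
    them unless listed in *keep*.
    """
    keep = set(keep or ())
    last_use: dict[str, int] = {}
    for i, node in enumerate(model.nodes):
        for src in node.inputs:
            last_use[src] = i
    acts: dict[str, np.ndarray] = {}
    out: dict[str, np.ndarray] = {}
    for i, node in enumerate(model.nodes):
        ins = [acts[s] for s in node.inputs]
        if node.op == "input":
            val = x
        elif node.op == "conv":
            spec = node.conv
            if spec.kernel is None:
                raise GraphError(f"{node.id}: weights not initialized")
            val = conv2d_same(ins[0], spec.kernel, spec.bias, spec.stride)
            val = apply_activation(val, spec.activation)
        elif node.op == "maxpool2":
            val = maxpool2(ins[0])
        elif node.op == "upsample2":
            val = upsample2(ins[0])
        elif node.op == "concat":
            val = np.concatenate(ins, axis=-1)
        elif node.op == "add":
            val = ins[0] + ins[1]
        elif node.op == "relu":
            val = np.maximum(ins[0], 0.0)
        else:  # pragma: no cover - validate() rejects unknown ops
            raise GraphError(node.op)
        acts[node.id] = val
        if node.id in keep or node is model.nodes[-1]:
            out[node.id] = val
        for src in node.inputs:
            if last_use.get(src) == i and src not in keep:
                acts.pop(src, None)
    return out


def forward(model: ModelSpec, image: np.ndarray) -> np.ndarray:
    """Probability map in (0, 1) for one image or an NHWC batch.

    ``image`` may be (H, W), (H, W, C) or (N, H, W, C); the result drops
    the trailing singleton channel and, for single images, the batch axis.
    """
    x = np.asarray(image, dtype=np.float32)
    single = x.ndim < 4
    if x.ndim == 2:
        x = x[..., None]
    if x.ndim == 3:
        x = x[None]
    if x.shape[1:] != model.input_shape:
        raise GraphError(
            f"image shape {x.shape[1:]} != model input {model.input_shape}")
    prob = evaluate(model, x)[model.output_id][..., 0]
    return prob[0] if single else prob


# ---------------------------------------------------------------------------
# subgraph builders
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MRBConfig:
    """Channel-preserving MultiRes block: branch widths are fixed sixths."""

    input_channels: int

    def __post_init__(self) -> None:
        if self.input_channels < 6 or self.input_channels % 6:
            raise GraphError(
                f"MultiRes block width {self.input_channels} must be a "
                "positive multiple of 6")

    @property
    def branch_channels(self) -> tuple[int, int, int]:
        c = self.input_channels
        return (c // 6, 2 * c // 6, 3 * c // 6)


@dataclass(frozen=True)
class ResPathConfig:
    channels: int
    repetitions: int = 4

    def __post_init__(self) -> None:
        if self.channels < 1:
            raise GraphError("residual path needs at least one channel")
        if self.repetitions != 4:
            raise GraphError(
                "the residual path is defined as exactly four repetitions "
                f"of the basic block, got {self.repetitions}")


class _Builder:
    """Accumulates nodes with unique ids."""

    def __init__(self) -> None:
        self.nodes: list[Node] = []

    def add(self, node: Node) -> str:
        self.nodes.append(node)
        return node.id

    def conv(self, nid: str, src: str, k: int, cin: int, cout: int,
             act: str, stage: int | None, kind: str) -> str:
        return self.add(Node(nid, "conv", (src,),
                             ConvSpec(k, 1, cin, cout, act),
                             stage=stage, kind=kind))


def _mrb(b: _Builder, prefix: str, src: str, cin: int, out: int,
         stage: int) -> str:
    """MultiRes block; identity shortcut iff cin == out, else 1x1 proj."""
    if out % 6:
        raise GraphError(
            f"{prefix}: MultiRes block output width {out} is not divisible "
            "by 6 (branch widths are out/6, out/3, out/2)")
    b1, b2, b3 = out // 6, 2 * out // 6, 3 * out // 6
    m1 = b.conv(f"{prefix}/m1", src, 3, cin, b1, "relu", stage, "feature")
    m2 = b.conv(f"{prefix}/m2", m1, 3, b1, b2, "relu", stage, "feature")
    m3 = b.conv(f"{prefix}/m3", m2, 3, b2, b3, "relu", stage, "feature")
    cc = b.add(Node(f"{prefix}/concat", "concat", (m1, m2, m3), stage=stage))
    if cin == out:
        shortcut = src
    else:
        shortcut = b.conv(f"{prefix}/proj", src, 1, cin, out, "linear",
                          stage, "skip")
    return b.add(Node(f"{prefix}/add", "add", (cc, shortcut), stage=stage))


def _respath(b: _Builder, prefix: str, src: str, cin: int, width: int,
             stage: int, repetitions: int = 4) -> str:
    c = cin
    for rep in range(1, repetitions + 1):
        c3 = b.conv(f"{prefix}/rep{rep}/conv3", src, 3, c, width, "relu",
                    stage, "skip")
        c1 = b.conv(f"{prefix}/rep{rep}/conv1", src, 1, c, width, "relu",
                    stage, "skip")
        src = b.add(Node(f"{prefix}/rep{rep}/add", "add", (c3, c1),
                         stage=stage, kind="skip"))
        c = width
    return src


def mrb_subgraph(cfg: MRBConfig) -> ModelSpec:
    """The channel-preserving MultiRes block as a standalone graph.

    Input and output widths are equal (the residual shortcut is the
    identity), so the block is exercised exactly as inside an encoder
    stage whose width does not change.
    """
    b = _Builder()
    b.add(Node("in", "input"))
    out = _mrb(b, "mrb", "in", cfg.input_channels, cfg.input_channels, 0)
    b.conv("out", out, 1, cfg.input_channels, 1, "sigmoid", 0, "output")
    return ModelSpec("mrb", b.nodes, (16, 16, cfg.input_channels))


def respath_subgraph(cfg: ResPathConfig) -> ModelSpec:
    """The four-repetition residual path as a standalone graph."""
    b = _Builder()
    b.add(Node("in", "input"))
    out = _respath(b, "rp", "in", cfg.channels, cfg.channels, 0,
                   cfg.repetitions)
    b.conv("out", out, 1, cfg.channels, 1, "sigmoid", 0, "output")
    return ModelSpec("respath", b.nodes, (16, 16, cfg.channels))


# ---------------------------------------------------------------------------
# full architectures
# ---------------------------------------------------------------------------

def _build_unet_family(name: str, encoder: Sequence[int],
                       decoder: Sequence[int],
                       input_shape: tuple[int, int, int]) -> ModelSpec:
    depth = len(encoder) - 1
    if len(decoder) != depth:
        raise GraphError(
            f"{name}: decoder needs {depth} widths, got {len(decoder)}")
    _check_divisible(name, input_shape, depth)
    cin = input_shape[2]
    b = _Builder()
    src = b.add(Node("in", "input"))
    skips: list[tuple[str, int]] = []
    c = cin
    for i, width in enumerate(encoder):
        if i > 0:
            src = b.add(Node(f"enc{i}/pool", "maxpool2", (src,), stage=i))
        src = b.conv(f"enc{i}/conv1", src, 3, c, width, "linear", i, "feature")
        src = b.conv(f"enc{i}/conv2", src, 3, width, width, "relu", i,
                     "feature")
        skips.append((src, width))
        c = width
    for j, width in enumerate(decoder):
        stage = depth + 1 + j
        skip_id, skip_c = skips[depth - 1 - j]
        up = b.add(Node(f"dec{stage}/up", "upsample2", (src,), stage=stage))
        src = b.add(Node(f"dec{stage}/concat", "concat", (skip_id, up),
                         stage=stage))
        src = b.conv(f"dec{stage}/conv1", src, 3, skip_c + c, width,
                     "linear", stage, "feature")
        src = b.conv(f"dec{stage}/conv2", src, 3, width, width, "relu",
                     stage, "feature")
        c = width
    b.conv("out", src, 1, c, 1, "sigmoid", 2 * depth, "output")
    return ModelSpec(name, b.nodes, tuple(input_shape))


def _build_multires_family(name: str, stem: int, blocks: Sequence[int],
                           respath: Sequence[int], decoder: Sequence[int],
                           input_shape: tuple[int, int, int]) -> ModelSpec:
    depth = len(blocks) - 1
    if len(respath) != depth or len(decoder) != depth:
        raise GraphError(
            f"{name}: needs {depth} respath and decoder widths, got "
            f"{len(respath)} and {len(decoder)}")
    _check_divisible(name, input_shape, depth)
    cin = input_shape[2]
    b = _Builder()
    src = b.add(Node("in", "input"))
    src = b.conv("stem", src, 3, cin, stem, "linear", 0, "feature")
    c = stem
    skips: list[tuple[str, int]] = []
    for i, width in enumerate(blocks):
        if i > 0:
            src = b.add(Node(f"enc{i}/pool", "maxpool2", (src,), stage=i))
        src = _mrb(b, f"enc{i}/mrb", src, c, width, i)
        src = b.add(Node(f"enc{i}/relu", "relu", (src,), stage=i))
        skips.append((src, width))
        c = width
    for j, width in enumerate(decoder):
        stage = depth + 1 + j
        lev = depth - 1 - j
        skip_id, skip_c = skips[lev]
        rp = _respath(b, f"rp{lev}", skip_id, skip_c, respath[lev], stage)
        up = b.add(Node(f"dec{stage}/up", "upsample2", (src,), stage=stage))
        src = b.add(Node(f"dec{stage}/concat", "concat", (rp, up),
                         stage=stage))
        src = _mrb(b, f"dec{stage}/mrb", src, respath[lev] + c, width, stage)
        src = b.add(Node(f"dec{stage}/relu", "relu", (src,), stage=stage))
        c = width
    b.conv("out", src, 1, c, 1, "sigmoid", 2 * depth, "output")
    return ModelSpec(name, b.nodes, tuple(input_shape))


def _check_divisible(name: str, input_shape, depth: int) -> None:
    h, w, _ = input_shape
    div = 1 << depth
    if h % div or w % div:
        raise GraphError(
            f"{name}: input {h}x{w} must be divisible by {div}")


_STAGE_COUNTS = {  # encoder widths incl. bottleneck, per architecture
    "unet": 5, "half_unet": 3,
    "multiresunet": 5, "half_multiresunet": 3, "quarter_multiresunet": 2,
}


def default_config(name: str) -> dict:
    """Load the packaged width table for one of the five architectures."""
    if name not in ARCH_NAMES:
        raise GraphError(f"unknown architecture {name!r}; "
                         f"expected one of {ARCH_NAMES}")
    text = resources.files("tinyseg.configs").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


def build_model(name: str, config: Mapping | None = None,
                input_shape: tuple[int, int, int] | None = None) -> ModelSpec:
    """Construct one of the five architectures as a validated ModelSpec.

    Parameters
    ----------
    name:
        One of ``unet``, ``half_unet``, ``multiresunet``,
        ``half_multiresunet``, ``quarter_multiresunet``.
    config:
        Width table; defaults to the packaged per-architecture YAML whose
        parameter and FLOP totals reproduce the published complexity
        figures.  Keys: ``encoder``/``decoder`` for the plain family,
        ``stem``/``blocks``/``respath``/``decoder`` for the MultiRes
        family.
    input_shape:
        (H, W, C); defaults to the config's ``input_shape``.
    """
    cfg = dict(default_config(name))
    if config is not None:
        cfg.update(config)
    shape = tuple(input_shape or cfg.get("input_shape"))
    if name in ("unet", "half_unet"):
        enc = list(cfg["encoder"])
        if len(enc) != _STAGE_COUNTS[name]:
            raise GraphError(
                f"{name}: expected {_STAGE_COUNTS[name]} encoder widths "
                f"(incl. bottleneck), got {len(enc)}")
        return _build_unet_family(name, enc, list(cfg["decoder"]), shape)
    blocks = list(cfg["blocks"])
    if len(blocks) != _STAGE_COUNTS[name]:
        raise GraphError(
            f"{name}: expected {_STAGE_COUNTS[name]} block widths "
            f"(incl. bottleneck), got {len(blocks)}")
    return _build_multires_family(name, int(cfg["stem"]), blocks,
                                  list(cfg["respath"]), list(cfg["decoder"]),
                                  shape)
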