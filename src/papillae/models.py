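"""The three encoder-decoder architectures for papilla heatmap regression.

All three networks map an H x W image (1 or 3 channels) to a single-channel
continuous heatmap of identical spatial size, ending in a *linear* 1x1
regression head:

* ``classic_unet`` — standard 4-level U-Net, encoder widths 64/128/256/512,
  1024-filter middle block, plain skip concatenation.
* ``optimized_unet`` — slimmed filter plan (64, 64, 128, 256; middle 512)
  with BatchNorm after every convolution and Dropout in each block.
* ``multires_unet`` — MultiRes blocks (three chained 3x3 convolutions whose
  outputs are concatenated plus a 1x1 residual) and residual skip paths,
  with the usual width plan of base 32 scaled by alpha = 1.67.

Architectures are declarative (:class:`ArchitectureSpec` -> LayerDef graph),
so parameter counts are available without allocating weights, and structure
can be inspected in tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .core import Heatmap, ImageGrid
from .errors import ValidationError
from .nn import LayerDef, Network, count_graph_parameters

VALID_NAMES = ("classic_unet", "multires_unet", "optimized_unet")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Declarative description of one network.

    ``encoder_filters`` lists per-stage output widths (for the MultiRes
    variant these are the block totals derived from ``multires_base`` and
    ``multires_alpha``); ``decoder_filters`` must mirror them. The final
    activation is linear for every variant — the networks regress a
    continuous map, not a class mask.
    """

    name: str
    encoder_filters: tuple[int, ...]
    middle_filters: int
    decoder_filters: tuple[int, ...]
    use_batch_norm: bool
    dropout_rate: float
    input_channels: int = 3
    final_activation: str = "linear"
    multires_base: int = 0      # only used by multires_unet
    multires_alpha: float = 1.67

    def __post_init__(self) -> None:
        if self.name not in VALID_NAMES:
            raise ValidationError(f"unknown architecture {self.name!r}")
        if self.decoder_filters != tuple(reversed(self.encoder_filters)):
            raise ValidationError("decoder_filters must mirror encoder_filters")
        if not 0 <= self.dropout_rate < 1:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.input_channels not in (1, 3):
            raise ValidationError("input_channels must be 1 or 3")
        if self.final_activation != "linear":
            raise ValidationError("all architectures end in a linear head")

    @property
    def depth(self) -> int:
        return len(self.encoder_filters)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureSpec":
        d = json.loads(text)
        d["encoder_filters"] = tuple(d["encoder_filters"])
        d["decoder_filters"] = tuple(d["decoder_filters"])
        return cls(**d)


# ---------------------------------------------------------------------------
# Spec constructors
# ---------------------------------------------------------------------------

def classic_unet_spec(input_channels: int = 3) -> ArchitectureSpec:
    """Standard U-Net: widths double from 64 to a 1024-filter middle block."""
    enc = (64, 128, 256, 512)
    return ArchitectureSpec(
        name="classic_unet", encoder_filters=enc, middle_filters=1024,
        decoder_filters=tuple(reversed(enc)), use_batch_norm=False,
        dropout_rate=0.0, input_channels=input_channels,
    )


def optimized_unet_spec(input_channels: int = 3, dropout_rate: float = 0.2) -> ArchitectureSpec:
    """Slimmed U-Net: 64 filters in the first two blocks, 128, 256, middle
    512, BatchNorm after each convolution and Dropout in every block."""
    enc = (64, 64, 128, 256)
    return ArchitectureSpec(
        name="optimized_unet", encoder_filters=enc, middle_filters=512,
        decoder_filters=tuple(reversed(enc)), use_batch_norm=True,
        dropout_rate=dropout_rate, input_channels=input_channels,
    )


def _mrb_widths(w: float) -> tuple[int, int, int]:
    """Chained-conv widths of a MultiRes block of nominal width ``w``."""
    return int(w * 0.167), int(w * 0.333), int(w * 0.5)


def multires_unet_spec(input_channels: int = 3, base: int = 32,
                       alpha: float = 1.67) -> ArchitectureSpec:
    """MultiResUNet: block widths alpha * base * 2^level, residual skips."""
    totals = tuple(sum(_mrb_widths(alpha * base * 2 ** lvl)) for lvl in range(4))
    middle = sum(_mrb_widths(alpha * base * 16))
    return ArchitectureSpec(
        name="multires_unet", encoder_filters=totals, middle_filters=middle,
        decoder_filters=tuple(reversed(totals)), use_batch_norm=True,
        dropout_rate=0.0, input_channels=input_channels,
        multires_base=base, multires_alpha=alpha,
    )


def scale_spec(spec: ArchitectureSpec, factor: float) -> ArchitectureSpec:
    """Return a width-scaled copy of a spec (min width 4 per stage).

    Used by the desk-scale presets; depth and structure are unchanged.
    """
    if spec.name == "multires_unet":
        return multires_unet_spec(
            input_channels=spec.input_channels,
            base=max(4, int(round(spec.multires_base * factor))),
            alpha=spec.multires_alpha,
        )
    enc = tuple(max(4, int(round(f * factor))) for f in spec.encoder_filters)
    mid = max(4, int(round(spec.middle_filters * factor)))
    return ArchitectureSpec(
        name=spec.name, encoder_filters=enc, middle_filters=mid,
        decoder_filters=tuple(reversed(enc)), use_batch_norm=spec.use_batch_norm,
        dropout_rate=spec.dropout_rate, input_channels=spec.input_channels,
    )


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------

class _GraphBuilder:
    def __init__(self) -> None:
        self.nodes: list[LayerDef] = []
        self.channels: dict[str, int] = {}

    def add(self, name: str, op: str, inputs: tuple[str, ...], out_ch: int | None = None,
            kernel: int = 3, rate: float = 0.0) -> str:
        in_ch = self.channels[inputs[0]] if inputs else 0
        if op == "concat":
            out_ch = sum(self.channels[i] for i in inputs)
        elif out_ch is None:
            out_ch = in_ch
        self.nodes.append(LayerDef(name=name, op=op, inputs=inputs,
                                   in_channels=in_ch, out_channels=out_ch,
                                   kernel=kernel, rate=rate))
        self.channels[name] = out_ch
        return name

    def conv_bn_relu(self, prefix: str, x: str, out_ch: int, use_bn: bool,
                     kernel: int = 3, relu: bool = True) -> str:
        x = self.add(f"{prefix}", "conv", (x,), out_ch, kernel=kernel)
        if use_bn:
            x = self.add(f"{prefix}_bn", "bn", (x,))
        if relu:
            x = self.add(f"{prefix}_relu", "relu", (x,))
        return x


def _plain_block(b: _GraphBuilder, prefix: str, x: str, filters: int,
                 use_bn: bool, dropout: float) -> str:
    x = b.conv_bn_relu(f"{prefix}_conv1", x, filters, use_bn)
    x = b.conv_bn_relu(f"{prefix}_conv2", x, filters, use_bn)
    if dropout > 0:
        x = b.add(f"{prefix}_drop", "dropout", (x,), rate=dropout)
    return x


def _multires_block(b: _GraphBuilder, prefix: str, x: str, w: float) -> str:
    f1, f2, f3 = _mrb_widths(w)
    total = f1 + f2 + f3
    sc = b.conv_bn_relu(f"{prefix}_sc", x, total, use_bn=True, kernel=1, relu=False)
    c1 = b.conv_bn_relu(f"{prefix}_c1", x, f1, use_bn=True)
    c2 = b.conv_bn_relu(f"{prefix}_c2", c1, f2, use_bn=True)
    c3 = b.conv_bn_relu(f"{prefix}_c3", c2, f3, use_bn=True)
    cat = b.add(f"{prefix}_cat", "concat", (c1, c2, c3))
    cat = b.add(f"{prefix}_cat_bn", "bn", (cat,))
    out = b.add(f"{prefix}_add", "add", (cat, sc))
    out = b.add(f"{prefix}_out_relu", "relu", (out,))
    out = b.add(f"{prefix}_out_bn", "bn", (out,))
    return out


def _res_path(b: _GraphBuilder, prefix: str, x: str, filters: int, length: int) -> str:
    for i in range(length):
        sc = b.conv_bn_relu(f"{prefix}_u{i}_sc", x, filters, use_bn=True,
                            kernel=1, relu=False)
        main = b.conv_bn_relu(f"{prefix}_u{i}_c", x, filters, use_bn=True,
                              relu=False)
        x = b.add(f"{prefix}_u{i}_add", "add", (main, sc))
        x = b.add(f"{prefix}_u{i}_relu", "relu", (x,))
        x = b.add(f"{prefix}_u{i}_bn", "bn", (x,))
    return x


def build_graph(spec: ArchitectureSpec) -> list[LayerDef]:
    """Lower an ArchitectureSpec to the executable LayerDef DAG."""
    b = _GraphBuilder()
    b.channels["input"] = spec.input_channels
    b.nodes.append(LayerDef("input", "input", (), 0, spec.input_channels))
    x = "input"
    skips: list[str] = []

    if spec.name == "multires_unet":
        depth = spec.depth
        for lvl in range(depth):
            w = spec.multires_alpha * spec.multires_base * 2 ** lvl
            x = _multires_block(b, f"enc{lvl + 1}", x, w)
            skip = _res_path(b, f"skip{lvl + 1}", x,
                             spec.multires_base * 2 ** lvl, depth - lvl)
            skips.append(skip)
            x = b.add(f"pool{lvl + 1}", "maxpool", (x,))
        x = _multires_block(b, "mid", x, spec.multires_alpha * spec.multires_base * 2 ** depth)
        for lvl in reversed(range(depth)):
            up = b.add(f"up{lvl + 1}", "upconv", (x,), spec.multires_base * 2 ** lvl, kernel=2)
            x = b.add(f"cat{lvl + 1}", "concat", (up, skips[lvl]))
            x = _multires_block(b, f"dec{lvl + 1}", x,
                                spec.multires_alpha * spec.multires_base * 2 ** lvl)
    else:
        mid_dropout = 0.5 if spec.dropout_rate > 0 else 0.0
        for i, f in enumerate(spec.encoder_filters, start=1):
            x = _plain_block(b, f"enc{i}", x, f, spec.use_batch_norm, spec.dropout_rate)
            skips.append(x)
            x = b.add(f"pool{i}", "maxpool", (x,))
        x = _plain_block(b, "mid", x, spec.middle_filters, spec.use_batch_norm, mid_dropout)
        for i, f in zip(reversed(range(1, spec.depth + 1)), spec.decoder_filters):
            up = b.add(f"up{i}", "upconv", (x,), f, kernel=2)
            x = b.add(f"cat{i}", "concat", (up, skips[i - 1]))
            x = _plain_block(b, f"dec{i}", x, f, spec.use_batch_norm, spec.dropout_rate)

    b.add("head", "conv", (x,), 1, kernel=1)  # linear regression head
    return b.nodes


def count_parameters(spec: ArchitectureSpec) -> int:
    """Trainable scalars (kernels + biases + BN scales/shifts) of a spec."""
    return count_graph_parameters(build_graph(spec))


# ---------------------------------------------------------------------------
# Instantiation
# ---------------------------------------------------------------------------

@dataclass
class ModelHandle:
    """A built network plus its prediction contract.

    ``predict`` maps an image to a same-size single-channel heatmap; inputs
    whose sides are not divisible by 2^depth are reflection-padded up and
    the output is center-cropped back, so a 250x250 image yields a 250x250
    map. Inference runs with dropout disabled and BatchNorm in running-stats
    mode, hence is deterministic for fixed weights.
    """

    spec: ArchitectureSpec
    network: Network
    parameter_count: int

    def predict(self, image: ImageGrid | np.ndarray) -> Heatmap:
        raw = self.predict_raw(image)
        return Heatmap(np.clip(raw, 0.0, 1.0))

    def predict_raw(self, image: ImageGrid | np.ndarray) -> np.ndarray:
        """Unclipped network output (the linear head may leave [0, 1])."""
        px = image.pixels if isinstance(image, ImageGrid) else np.asarray(image)
        if px.ndim == 2:
            px = px[:, :, None]
        x = px.transpose(2, 0, 1)[None].astype(np.float32)
        y = forward_padded(self.network, x, training=False)
        return y[0, 0].astype(np.float32)


def pad_to_multiple(x: np.ndarray, multiple: int) -> tuple[np.ndarray, tuple[int, int]]:
    """Reflection-pad NCHW spatial dims up to the next multiple."""
    h, w = x.shape[2], x.shape[3]
    ph = (-h) % multiple
    pw = (-w) % multiple
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph // 2, ph - ph // 2),
                       (pw // 2, pw - pw // 2)), mode="reflect")
    return x, (ph, pw)


def forward_padded(net: Network, x: np.ndarray, training: bool = False,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Forward pass with automatic pad-to-/16 and center crop back."""
    h, w = x.shape[2], x.shape[3]
    xp, (ph, pw) = pad_to_multiple(x, 16)
    y, _ = net.forward(xp, training=training, rng=rng)
    return y[:, :, ph // 2: ph // 2 + h, pw // 2: pw // 2 + w]


def instantiate(spec: ArchitectureSpec, seed: int) -> ModelHandle:
    """Build a network with deterministic seeded initialization."""
    graph = build_graph(spec)
    net = Network.build(graph, seed=seed)
    n = net.parameter_count()
    expected = count_graph_parameters(graph)
    assert n == expected, f"parameter bookkeeping mismatch: {n} != {expected}"
    return ModelHandle(spec=spec, network=net, parameter_count=n)


def save_checkpoint(path: str | Path, handle: ModelHandle) -> None:
    """Save weights (npz) with the spec embedded for reload validation."""
    path = Path(path)
    flat: dict[str, np.ndarray] = {}
    for layer, d in handle.network.params.items():
        for name, arr in d.items():
            flat[f"param/{layer}/{name}"] = arr
    for layer, d in handle.network.bn_stats.items():
        for name, arr in d.items():
            flat[f"bn/{layer}/{name}"] = arr
    np.savez(path, __spec__=np.frombuffer(handle.spec.to_json().encode(), dtype=np.uint8), **flat)


def load_checkpoint(path: str | Path) -> ModelHandle:
    data = np.load(Path(path))
    spec = ArchitectureSpec.from_json(bytes(data["__spec__"]).decode())
    handle = instantiate(spec, seed=0)
    for key in data.files:
        if key == "__spec__":
            continue
        kind, layer, name = key.split("/")
        target = handle.network.params if kind == "param" else handle.network.bn_stats
        target[layer][name][...] = data[key]
    return handle
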