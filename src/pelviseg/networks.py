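"""Declarative construction of the three segmentation architectures.

All three networks share a 3D encoder–decoder backbone:

* four encoder resolutions (three stride-2 down-convolutions; no max-pooling),
  each level holding standard convolution blocks (3D conv + instance norm +
  dropout 0.2 + ReLU);
* additive skip connections (not concatenation) into three reconstruction
  stages, each an up-convolution with stride 2 followed by two standard
  convolution blocks;
* a final 1x1x1 convolution with softmax producing per-voxel channel
  probabilities.

``mnet`` adds a class-label branch: the per-case binary class vector,
broadcast to a constant (X,Y,Z,C) volume, passes through a convolution +
average-pooling chain producing one tensor per encoder resolution, each added
elementwise to the encoder feature map (a learned mask conditioning the
encoder on gross anatomical regime).  ``dmnet`` further inserts, between
encoder and decoder, three dilated convolution blocks (instance norm +
leaky-ReLU, no dropout) with equal dilation rates and decreasing filter
counts (4F, 2F, F), followed by one standard convolution block.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "BlockSpec",
    "NetworkSpec",
    "SegmentationNetwork",
    "build_network",
    "build_unet3d",
    "build_mnet",
    "build_dmnet",
    "transfer_weights",
    "save_checkpoint",
    "load_checkpoint",
]

_ARCH_NAMES = ("unet3d", "mnet", "dmnet")


@dataclass
class BlockSpec:
    """Declarative description of one convolutional block."""

    kind: str  # std_conv | dilated_conv | down_conv | up_conv | mask_inject | head
    filters: int
    kernel: int = 3
    stride: int = 1
    dilation_rate: int = 1
    activation: str = "relu"
    dropout_rate: float = 0.0

    def __post_init__(self):
        if self.kind == "std_conv":
            self.activation = "relu"
            self.dropout_rate = 0.2
        elif self.kind == "dilated_conv":
            self.activation = "leaky_relu"
            self.dropout_rate = 0.0
        elif self.kind == "head":
            self.kernel = 1
            self.activation = "softmax"


@dataclass
class NetworkSpec:
    name: str = "unet3d"
    input_shape: tuple[int, int, int, int] = (64, 64, 16, 1)
    n_classes: int = 4
    base_filters: int = 8
    levels: int = 4
    convs_per_level: int = 2
    dilation_rate: int = 2
    leaky_slope: float = 0.01
    class_input_shape: tuple[int, int, int, int] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.name not in _ARCH_NAMES:
            raise ValueError(f"unknown architecture {self.name!r}")
        if self.name in ("mnet", "dmnet"):
            if self.class_input_shape is None:
                self.class_input_shape = self.input_shape[:3] + (self.n_classes,)
            if self.class_input_shape[-1] != self.n_classes:
                raise ValueError(
                    "class input channel count must equal n_classes "
                    f"({self.class_input_shape[-1]} != {self.n_classes})"
                )

    def block_plan(self) -> list[BlockSpec]:
        """The ordered block graph (for introspection and documentation)."""
        F = self.base_filters
        blocks: list[BlockSpec] = []
        for lvl in range(self.levels):
            for _ in range(self.convs_per_level):
                blocks.append(BlockSpec("std_conv", F * 2**lvl))
            if self.name in ("mnet", "dmnet"):
                blocks.append(BlockSpec("mask_inject", F * 2**lvl))
            if lvl < self.levels - 1:
                blocks.append(BlockSpec("down_conv", F * 2 ** (lvl + 1), stride=2))
        if self.name == "dmnet":
            for mult in (4, 2, 1):
                blocks.append(
                    BlockSpec("dilated_conv", F * mult, dilation_rate=self.dilation_rate)
                )
            blocks.append(BlockSpec("std_conv", F))
        for lvl in reversed(range(self.levels - 1)):
            blocks.append(BlockSpec("up_conv", F * 2**lvl, kernel=2, stride=2))
            for _ in range(2):
                blocks.append(BlockSpec("std_conv", F * 2**lvl))
        blocks.append(BlockSpec("head", self.n_classes))
        return blocks


class _StdBlock(nn.Module):
    _wants_training = True

    def __init__(self, in_ch, out_ch, rng, dropout_rng):
        self.conv = nn.Conv3d(in_ch, out_ch, rng=rng)
        self.norm = nn.InstanceNorm(out_ch)
        self.drop = nn.Dropout(0.2, rng=dropout_rng)
        self.act = nn.ReLU()

    def forward(self, x, training=False):
        return self.act(self.drop(self.norm(self.conv(x)), training=training))


class _DilatedBlock(nn.Module):
    def __init__(self, in_ch, out_ch, dilation, slope, rng):
        self.conv = nn.Conv3d(in_ch, out_ch, dilation=dilation, rng=rng)
        self.norm = nn.InstanceNorm(out_ch)
        self.act = nn.LeakyReLU(slope)
        self.dilation = dilation

    def forward(self, x, training=False):
        return self.act(self.norm(self.conv(x)))


class SegmentationNetwork(nn.Module):
    """Executable encoder–bottleneck–decoder network built from a spec."""

    def __init__(self, spec: NetworkSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        self.dropout_rng = np.random.default_rng(spec.seed + 1)
        F = spec.base_filters
        L = spec.levels
        masked = spec.name in ("mnet", "dmnet")

        self.enc = []
        in_ch = spec.input_shape[-1]
        for lvl in range(L):
            ch = F * 2**lvl
            stack = []
            for _ in range(spec.convs_per_level):
                stack.append(_StdBlock(in_ch, ch, rng, self.dropout_rng))
                in_ch = ch
            self.enc.append(nn.Sequential(*stack))
            if lvl < L - 1:
                in_ch = F * 2 ** (lvl + 1)  # the stride-2 down-conv's output
        self.down = [
            nn.Conv3d(F * 2**lvl, F * 2 ** (lvl + 1), stride=2, rng=rng)
            for lvl in range(L - 1)
        ]

        if masked:
            self.mask_conv = []
            mc_in = spec.n_classes
            for lvl in range(L):
                ch = F * 2**lvl
                self.mask_conv.append(nn.Conv3d(mc_in, ch, rng=rng))
                mc_in = ch
            self.mask_pool = nn.AvgPool2()

        if spec.name == "dmnet":
            deep = F * 2 ** (L - 1)
            self.dcl = []
            dcl_in = deep
            for mult in (4, 2, 1):
                self.dcl.append(
                    _DilatedBlock(dcl_in, F * mult, spec.dilation_rate, spec.leaky_slope, rng)
                )
                dcl_in = F * mult
            self.bottleneck_conv = _StdBlock(dcl_in, F, rng, self.dropout_rng)
            dec_in = F
        else:
            dec_in = F * 2 ** (L - 1)

        self.up = []
        self.dec = []
        for lvl in reversed(range(L - 1)):
            ch = F * 2**lvl
            self.up.append(nn.UpConv3d(dec_in, ch, rng=rng))
            self.dec.append(
                nn.Sequential(
                    _StdBlock(ch, ch, rng, self.dropout_rng),
                    _StdBlock(ch, ch, rng, self.dropout_rng),
                )
            )
            dec_in = ch
        self.head = nn.Conv3d(dec_in, spec.n_classes, kernel=1, rng=rng)
        self.softmax = nn.Softmax()

    # -- execution ---------------------------------------------------------

    def _check_input(self, image: np.ndarray) -> None:
        div = 2 ** (self.spec.levels - 1)
        bad = [n for n in image.shape[:3] if n % div]
        if bad:
            raise ValueError(
                f"spatial extents {image.shape[:3]} must be divisible by {div}"
            )

    def forward(self, image, class_volume=None, training: bool = False,
                return_features: bool = False):
        """Run the network on one channel-last volume.

        ``image``: array or Tensor (X,Y,Z,1); ``class_volume``: constant
        (X,Y,Z,C) array, required for mnet/dmnet.  Returns the softmax output
        (X,Y,Z,C); with ``return_features=True`` also the penultimate
        (pre-head) feature tensor.
        """
        if isinstance(image, Tensor):
            x = image
        else:
            arr = np.asarray(_np(image), dtype=np.float32)
            if arr.ndim == 3:
                arr = arr[..., None]
            x = nn.as_tensor(arr)
        self._check_input(x.data)
        masked = self.spec.name in ("mnet", "dmnet")
        if masked:
            if class_volume is None:
                raise ValueError(f"{self.spec.name} requires a class-label volume")
            cv = np.asarray(_np(class_volume), dtype=np.float32)
            if cv.shape[-1] != self.spec.n_classes:
                raise ValueError(
                    f"class volume has {cv.shape[-1]} channels, "
                    f"expected {self.spec.n_classes}"
                )
            m = nn.as_tensor(cv)
            mask_feats = []
            for lvl in range(self.spec.levels):
                if lvl > 0:
                    m = self.mask_pool(m)
                m = self.mask_conv[lvl](m)
                mask_feats.append(m)

        skips = []
        h = x
        for lvl in range(self.spec.levels):
            h = self.enc[lvl](h, training=training)
            if masked:
                h = h + mask_feats[lvl]
            if lvl < self.spec.levels - 1:
                skips.append(h)
                h = self.down[lvl](h)

        if self.spec.name == "dmnet":
            for block in self.dcl:
                h = block(h, training=training)
            h = self.bottleneck_conv(h, training=training)

        for i, lvl in enumerate(reversed(range(self.spec.levels - 1))):
            h = self.up[i](h)
            h = h + skips[lvl]
            h = self.dec[i](h, training=training)

        out = self.softmax(self.head(h))
        if return_features:
            return out, h
        return out

    def parameter_count(self) -> int:
        return sum(p.data.size for p in self.parameters().values())


def _np(x):
    return getattr(x, "data", x)


def build_unet3d(spec: NetworkSpec) -> SegmentationNetwork:
    if spec.name != "unet3d":
        raise ValueError("spec.name must be 'unet3d'")
    return SegmentationNetwork(spec)


def build_mnet(spec: NetworkSpec) -> SegmentationNetwork:
    if spec.name != "mnet":
        raise ValueError("spec.name must be 'mnet'")
    return SegmentationNetwork(spec)


def build_dmnet(spec: NetworkSpec) -> SegmentationNetwork:
    if spec.name != "dmnet":
        raise ValueError("spec.name must be 'dmnet'")
    return SegmentationNetwork(spec)


def build_network(spec: NetworkSpec) -> SegmentationNetwork:
    return {"unet3d": build_unet3d, "mnet": build_mnet, "dmnet": build_dmnet}[spec.name](spec)


# ---------------------------------------------------------------------------
# weight transfer and checkpoints


def transfer_weights(source: SegmentationNetwork, target_spec: NetworkSpec,
                     ) -> tuple[SegmentationNetwork, dict]:
    """Warm-start a new network from a trained one.

    Every parameter tensor with matching name and shape is copied; the output
    head is freshly initialised when the class counts differ.  Returns the new
    network and a manifest listing copied vs reinitialised tensor names.
    """
    if source.spec.name != target_spec.name or source.spec.base_filters != target_spec.base_filters:
        raise ValueError(
            "transfer requires matching architecture name and base_filters "
            f"({source.spec.name}/{source.spec.base_filters} vs "
            f"{target_spec.name}/{target_spec.base_filters})"
        )
    target = build_network(target_spec)
    src_params = source.parameters()
    tgt_params = target.parameters()
    head_fresh = source.spec.n_classes != target_spec.n_classes
    copied, reinit = [], []
    for name, tgt in tgt_params.items():
        src = src_params.get(name)
        is_head = name.startswith("head.") or (
            head_fresh and name.startswith("mask_conv.0.")
        )
        if src is not None and src.data.shape == tgt.data.shape and not (
            head_fresh and is_head
        ):
            tgt.data = src.data.copy()
            copied.append(name)
        else:
            reinit.append(name)
    if not copied:
        raise ValueError("no parameter tensor matched: wrong architecture pairing")
    manifest = {"copied": copied, "reinitialized": reinit}
    return target, manifest


def save_checkpoint(net: SegmentationNetwork, path: str | Path) -> None:
    """Save parameters as .npz plus a JSON manifest of tensor names/shapes."""
    path = Path(path)
    params = net.parameters()
    np.savez(path, **{k: p.data for k, p in params.items()})
    spec = net.spec
    manifest = {
        "spec": {k: (list(v) if isinstance(v, tuple) else v)
                 for k, v in vars(spec).items()},
        "tensors": {k: list(p.data.shape) for k, p in params.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_checkpoint(path: str | Path) -> SegmentationNetwork:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    kwargs = dict(manifest["spec"])
    for key in ("input_shape", "class_input_shape"):
        if kwargs.get(key) is not None:
            kwargs[key] = tuple(kwargs[key])
    spec = NetworkSpec(**kwargs)
    net = build_network(spec)
    if not path.exists() and path.with_suffix(".npz").exists():
        path = path.with_suffix(".npz")
    data = np.load(str(path))
    for name, p in net.parameters().items():
        p.data = data[name].copy()
    return net
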