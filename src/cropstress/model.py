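"""WF-UNet++: multi-head nested-skip encoder-decoder for five-class
crop-stress segmentation.

The backbone is a UNet++ lattice: encoder nodes X(i,0) at resolution
level i feed nested nodes X(i,j) = block(concat(X(i,0..j-1),
up(X(i+1,j-1)))) so every decoder node sees all same-level predecessors
plus an upsampled coarser feature.  Three heads read the final
full-resolution node X(0,L): a 1x1-conv segmentation head with softmax
over K = 5 classes, a 1x1-conv edge head with sigmoid, and a small conv
stack + tanh regression head for the normalized signed distance
transform.  A wavelet enhancement optionally concatenates single-level
Haar detail bands of each block input, giving the convolutions explicit
access to local high-frequency structure.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from cropstress.nn import Tensor, concat, ops
from cropstress.nn.layers import Module, Conv2d, BatchNorm2d, ConvBlock


@dataclass
class ModelConfig:
    in_channels: int = 6
    num_classes: int = 5
    depth: int = 4
    base_filters: int = 32
    wavelet_enabled: bool = True
    edge_head: bool = True
    sdt_head: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")


@dataclass
class NetworkOutputs:
    logits: Tensor
    probs: Tensor
    edge_probs: Tensor | None = None
    sdt_pred: Tensor | None = None


def haar_details(x: Tensor) -> tuple[Tensor, Tensor, Tensor]:
    """Single-level 2-D Haar detail sub-bands of an NCHW tensor.

    Returns (row-detail, column-detail, diagonal-detail) at half
    resolution; a constant input yields all-zero bands.  Odd spatial dims
    are edge-padded before the decomposition.
    """
    _, _, h, w = x.shape
    if h % 2:
        x = concat([x, x[:, :, -1:, :]], axis=2)
    if w % 2:
        x = concat([x, x[:, :, :, -1:]], axis=3)
    a = x[:, :, 0::2, 0::2]
    b = x[:, :, 0::2, 1::2]
    c = x[:, :, 1::2, 0::2]
    d = x[:, :, 1::2, 1::2]
    detail_rows = (a + b - c - d) * 0.5  # difference across row pairs
    detail_cols = (a - b + c - d) * 0.5  # difference across column pairs
    detail_diag = (a - b - c + d) * 0.5
    return detail_rows, detail_cols, detail_diag


def wavelet_enhance(x: Tensor) -> Tensor:
    """Concatenate channel-averaged Haar detail bands to the feature tensor.

    The three detail sub-bands are averaged over channels, upsampled back
    to the input resolution, and appended as three extra channels, so
    each block's convolutions see explicit high-frequency structure at
    marginal parameter cost.
    """
    _, _, h, w = x.shape
    bands = []
    for band in haar_details(x):
        band = band.mean(axis=1, keepdims=True)
        band = ops.upsample_nearest2x(band)
        bands.append(band[:, :, :h, :w])
    return concat([x] + bands, axis=1)


class _UpProject(Module):
    """Bilinear 2x upsampling followed by a 1x1 channel projection."""

    def __init__(self, in_ch: int, out_ch: int, rng=None):
        super().__init__()
        self.proj = Conv2d(in_ch, out_ch, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.proj(ops.upsample_bilinear2x(x))


class _SDTHead(Module):
    def __init__(self, in_ch: int, rng=None):
        super().__init__()
        self.conv = Conv2d(in_ch, in_ch, 3, rng=rng)
        self.bn = BatchNorm2d(in_ch)
        self.proj = Conv2d(in_ch, 1, kernel=1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.bn(self.conv(x)).relu()
        return self.proj(h).tanh()


class WFUNetPP(Module):
    def __init__(self, config: ModelConfig):
        super().__init__()
        self.config = config
        rng = np.random.default_rng(config.seed)
        L = config.depth
        filters = [config.base_filters * 2**i for i in range(L + 1)]
        extra = 3 if config.wavelet_enabled else 0

        self.blocks: dict = {}
        block_list = []  # keeps Module discovery simple
        up_list = []
        self.ups: dict = {}
        for i in range(L + 1):
            in_ch = config.in_channels if i == 0 else filters[i - 1]
            blk = ConvBlock(in_ch + extra, filters[i], rng=rng)
            self.blocks[(i, 0)] = blk
            block_list.append(blk)
        for j in range(1, L + 1):
            for i in range(0, L - j + 1):
                up = _UpProject(filters[i + 1], filters[i], rng=rng)
                self.ups[(i, j)] = up
                up_list.append(up)
                in_ch = (j + 1) * filters[i]
                blk = ConvBlock(in_ch + extra, filters[i], rng=rng)
                self.blocks[(i, j)] = blk
                block_list.append(blk)
        self._block_list = block_list
        self._up_list = up_list

        top = filters[0]
        self.seg_head = Conv2d(top, config.num_classes, kernel=1, rng=rng)
        self.edge_head = Conv2d(top, 1, kernel=1, rng=rng) if config.edge_head else None
        self.sdt_head = _SDTHead(top, rng=rng) if config.sdt_head else None

    # -- forward ----------------------------------------------------------

    def _run_block(self, key, x: Tensor) -> Tensor:
        if self.config.wavelet_enabled:
            x = wavelet_enhance(x)
        return self.blocks[key](x)

    def forward(self, x) -> NetworkOutputs:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected NCHW input with {self.config.in_channels} channels")
        L = self.config.depth
        if x.shape[2] % 2**L or x.shape[3] % 2**L:
            raise ValueError(f"spatial dims must be divisible by 2^{L}")

        nodes: dict = {}
        for i in range(L + 1):
            inp = x if i == 0 else ops.maxpool2x2(nodes[(i - 1, 0)])
            nodes[(i, 0)] = self._run_block((i, 0), inp)
        for j in range(1, L + 1):
            for i in range(0, L - j + 1):
                up = self.ups[(i, j)](nodes[(i + 1, j - 1)])
                inp = concat([nodes[(i, jj)] for jj in range(j)] + [up], axis=1)
                nodes[(i, j)] = self._run_block((i, j), inp)

        top = nodes[(0, L)]
        logits = self.seg_head(top)
        probs = ops.softmax_channels(logits)
        edge = self.edge_head(top).sigmoid()[:, 0] if self.edge_head is not None else None
        sdt = self.sdt_head(top)[:, 0] if self.sdt_head is not None else None
        return NetworkOutputs(logits=logits, probs=probs, edge_probs=edge, sdt_pred=sdt)

    @property
    def num_nodes(self) -> int:
        return len(self.blocks)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    # -- persistence ------------------------------------------------------

    def save(self, path) -> None:
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            json.dumps(asdict(self.config)).encode(), dtype=np.uint8
        )
        np.savez_compressed(str(path), **state)

    @classmethod
    def load(cls, path) -> "WFUNetPP":
        with np.load(str(path)) as data:
            cfg = ModelConfig(**json.loads(bytes(data["__config__"]).decode()))
            model = cls(cfg)
            model.load_state_dict({k: data[k] for k in data.files if k != "__config__"})
        return model


def build_model(config: ModelConfig) -> WFUNetPP:
    return WFUNetPP(config)
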