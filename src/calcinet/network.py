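"""Dual-branch fully convolutional network.

A depth-``d`` U-Net encoder-decoder (two 3x3 convs + ReLU per block, 2x2 max
pooling down, bilinear 2x up with skip concatenation) whose segmentation head
is three final convolutions (3x3 + ReLU, 3x3 + ReLU, 1x1 to class scores).
A classification branch taps the bottleneck feature map: a single 3x3
convolution, a double 3x3 convolutional block, a 1x1 output convolution,
then global average pooling and a softmax over the class scores.

The network is fully convolutional: any input whose sides are divisible by
``2^(depth-1)`` yields a segmentation map of identical spatial size.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .config import NetworkConfig
from .nn import Adam, BilinearUp2, Conv2d, GlobalAvgPool, MaxPool2, Param, ReLU, Sequential, double_conv

CHECKPOINT_VERSION = 1


@dataclass
class NetworkOutput:
    seg_scores: np.ndarray  # (n, n_seg_classes, h, w), unnormalized
    cls_scores: np.ndarray  # (n, n_cls_classes), unnormalized
    cls_probs: np.ndarray   # softmax of cls_scores


def _softmax(z: np.ndarray) -> np.ndarray:
    e = np.exp(z - z.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


class DualBranchNet:
    def __init__(self, config: NetworkConfig, rng: Optional[np.random.Generator] = None):
        config.validate()
        self.config = config
        rng = rng if rng is not None else np.random.default_rng(0)
        d, b = config.depth, config.base_channels

        self.enc_blocks = []
        self.pools = []
        cin = config.in_channels
        for lvl in range(d - 1):
            cout = b * 2**lvl
            self.enc_blocks.append(double_conv(cin, cout, f"enc{lvl}", rng))
            self.pools.append(MaxPool2())
            cin = cout
        cb = b * 2 ** (d - 1)
        self.bottleneck = double_conv(cin, cb, "bottleneck", rng)

        self.ups = []
        self.dec_blocks = []
        for lvl in reversed(range(d - 1)):
            skip_c = b * 2**lvl
            below_c = b * 2 ** (lvl + 1)
            self.ups.append(BilinearUp2())
            self.dec_blocks.append(double_conv(below_c + skip_c, skip_c, f"dec{lvl}", rng))

        self.seg_head = Sequential(
            Conv2d(b, b, 3, "seg.conv1", rng),
            ReLU(),
            Conv2d(b, b, 3, "seg.conv2", rng),
            ReLU(),
            Conv2d(b, config.n_seg_classes, 1, "seg.out", rng),
        )
        self.cls_branch = Sequential(
            Conv2d(cb, cb, 3, "cls.conv1", rng),
            ReLU(),
            Conv2d(cb, cb, 3, "cls.conv2", rng),
            ReLU(),
            Conv2d(cb, cb, 3, "cls.conv3", rng),
            ReLU(),
            Conv2d(cb, config.n_cls_classes, 1, "cls.out", rng),
        )
        self.cls_pool = GlobalAvgPool()
        self._skip_channels = [b * 2**lvl for lvl in range(d - 1)]

    # -- parameter plumbing -------------------------------------------------

    def parameters(self) -> List[Param]:
        out = []
        for blk in self.enc_blocks:
            out.extend(blk.params())
        out.extend(self.bottleneck.params())
        for blk in self.dec_blocks:
            out.extend(blk.params())
        out.extend(self.seg_head.params())
        out.extend(self.cls_branch.params())
        return out

    def n_parameters(self) -> int:
        return int(sum(p.value.size for p in self.parameters()))

    def state_dict(self) -> dict:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict) -> None:
        for p in self.parameters():
            if p.name not in state:
                raise KeyError(f"missing parameter {p.name}")
            if state[p.name].shape != p.value.shape:
                raise ValueError(f"shape mismatch for {p.name}")
            p.value[...] = state[p.name]

    # -- forward / backward -------------------------------------------------

    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None, None]
        elif x.ndim == 3:
            x = x[:, None]
        if x.ndim != 4 or x.shape[1] != self.config.in_channels:
            raise ValueError(f"expected (n, {self.config.in_channels}, h, w) input")
        stride = 2 ** (self.config.depth - 1)
        if x.shape[2] % stride or x.shape[3] % stride:
            raise ValueError(f"spatial dims must be divisible by {stride}")
        return x

    def forward(self, x: np.ndarray) -> NetworkOutput:
        x = self._check_input(x)
        skips = []
        for blk, pool in zip(self.enc_blocks, self.pools):
            s = blk.forward(x)
            skips.append(s)
            x = pool.forward(s)
        bott = self.bottleneck.forward(x)

        y = bott
        for up, blk, skip in zip(self.ups, self.dec_blocks, reversed(skips)):
            y = up.forward(y)
            y = np.concatenate([skip, y], axis=1)
            y = blk.forward(y)
        seg_scores = self.seg_head.forward(y)

        c = self.cls_branch.forward(bott)
        cls_scores = self.cls_pool.forward(c)
        return NetworkOutput(
            seg_scores=seg_scores,
            cls_scores=cls_scores,
            cls_probs=_softmax(cls_scores),
        )

    def backward(self, dseg_scores: np.ndarray, dcls_scores: np.ndarray) -> None:
        """Accumulate parameter gradients; call right after :meth:`forward`."""
        dc = self.cls_pool.backward(dcls_scores)
        dbott_cls = self.cls_branch.backward(dc)

        dy = self.seg_head.backward(dseg_scores)
        dskips = []
        for up, blk in zip(reversed(self.ups), reversed(self.dec_blocks)):
            dcat = blk.backward(dy)
            # forward concatenated [skip, below] with skip : below = 1 : 2
            n_skip = dcat.shape[1] // 3
            dskip, dbelow = dcat[:, :n_skip], dcat[:, n_skip:]
            dskips.append(dskip)
            dy = up.backward(dbelow)
        dbott = dy + dbott_cls

        dx = self.bottleneck.backward(dbott)
        for pool, blk, dskip in zip(
            reversed(self.pools), reversed(self.enc_blocks), reversed(dskips)
        ):
            ds = pool.backward(dx) + dskip
            dx = blk.backward(ds)

    # -- checkpointing ------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "version": CHECKPOINT_VERSION,
            "config": {
                "depth": self.config.depth,
                "base_channels": self.config.base_channels,
                "n_seg_classes": self.config.n_seg_classes,
                "n_cls_classes": self.config.n_cls_classes,
                "input_size": self.config.input_size,
                "in_channels": self.config.in_channels,
            },
        }
        with zipfile.ZipFile(path, "w") as zf:
            zf.writestr("meta.json", json.dumps(meta))
            buf = io.BytesIO()
            np.savez(buf, **self.state_dict())
            zf.writestr("weights.npz", buf.getvalue())

    @classmethod
    def load(cls, path) -> "DualBranchNet":
        with zipfile.ZipFile(path) as zf:
            meta = json.loads(zf.read("meta.json"))
            if meta.get("version") != CHECKPOINT_VERSION:
                raise ValueError(f"unsupported checkpoint version {meta.get('version')}")
            with zf.open("weights.npz") as fh:
                state = dict(np.load(io.BytesIO(fh.read())))
        net = cls(NetworkConfig(**meta["config"]))
        net.load_state_dict(state)
        return net


def build_network(config: NetworkConfig, rng: Optional[np.random.Generator] = None) -> DualBranchNet:
    """He-initialized network; weights are reproducible from ``rng``."""
    return DualBranchNet(config, rng=rng)
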