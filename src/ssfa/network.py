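"""Dual-branch encoder–decoder segmentation networks.

The architecture is a plain UNet whose encoder is split into two streams: a
Raw Image Encoder over the grayscale image and an FA Encoder over the
3-channel fracture-attention map.  At every resolution level the two feature
maps are fused by element-wise multiplication before downsampling; the fused
product feeds both the skip connection and the next image-encoder level, while
the FA stream continues with its own (un-fused) features.  Three fusion
variants are supported:

``multiple``
    FA Encoder mirrors every image-encoder level; fusion at each level.
``single``
    One FA block and one multiplication at the first level only.
``channel``
    No FA Encoder; the attention map is concatenated to the image as extra
    input channels.
``none``
    A plain single-encoder UNet over the image alone (used for supervised
    pretraining and as the baseline).

The FA stream ends each level with a ``1 + tanh`` activation, so its features
lie in (0, 2) and an all-zero attention map multiplies by ~1 instead of
annihilating the image features.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn

FUSIONS = ("channel", "single", "multiple", "none")


@dataclass
class NetworkSpec:
    """Architecture hyperparameters.

    depth is the number of resolution levels; spatial input dims must be
    divisible by 2**(depth-1).  base_channels can be reduced (e.g. to 8) for
    CPU-scale experiments.
    """

    depth: int = 5
    base_channels: int = 64
    fusion: str = "multiple"
    in_channels_image: int = 1
    in_channels_fa: int = 3
    out_classes: int = 2
    norm_groups: int = 8

    def __post_init__(self):
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.fusion not in FUSIONS:
            raise ValueError(f"unknown fusion {self.fusion!r}; expected one of {FUSIONS}")

    def channels(self) -> list[int]:
        return [min(self.base_channels * 2 ** i, self.base_channels * 8)
                for i in range(self.depth)]


def _groups(spec: NetworkSpec, c: int) -> int:
    g = min(spec.norm_groups, c)
    while c % g:
        g -= 1
    return g


class Predictor:
    """A trainable segmentation function (image, FA map) -> foreground probability."""

    def __init__(self, spec: NetworkSpec, seed: int):
        self.spec = spec
        self.init_seed = int(seed)
        self.trained = False
        self.params: dict[str, nn.Tensor] = {}
        self._build(np.random.default_rng(seed))

    # ------------------------------------------------------------ building

    def _conv(self, rng, name, cin, cout):
        std = np.sqrt(2.0 / (cin * 9))
        self.params[f"{name}.w"] = nn.Tensor(
            rng.normal(0.0, std, size=(3, 3, cin, cout)).astype(np.float32),
            requires_grad=True)
        self.params[f"{name}.b"] = nn.Tensor(
            np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.params[f"{name}.g"] = nn.Tensor(
            np.ones(cout, dtype=np.float32), requires_grad=True)
        self.params[f"{name}.beta"] = nn.Tensor(
            np.zeros(cout, dtype=np.float32), requires_grad=True)

    def _block(self, rng, name, cin, cout):
        self._conv(rng, f"{name}.0", cin, cout)
        self._conv(rng, f"{name}.1", cout, cout)

    def _build(self, rng):
        s = self.spec
        ch = s.channels()
        cin_img = s.in_channels_image
        if s.fusion == "channel":
            cin_img += s.in_channels_fa
        prev = cin_img
        for i, c in enumerate(ch):
            self._block(rng, f"enc{i}", prev, c)
            prev = c
        if s.fusion == "multiple":
            prev_fa = s.in_channels_fa
            for i, c in enumerate(ch):
                self._block(rng, f"fa{i}", prev_fa, c)
                prev_fa = c
        elif s.fusion == "single":
            self._block(rng, "fa0", s.in_channels_fa, ch[0])
        for i in range(s.depth - 2, -1, -1):
            self._block(rng, f"dec{i}", ch[i] + ch[i + 1], ch[i])
        std = np.sqrt(2.0 / ch[0])
        self.params["head.w"] = nn.Tensor(
            rng.normal(0.0, std, size=(ch[0], s.out_classes)).astype(np.float32),
            requires_grad=True)
        self.params["head.b"] = nn.Tensor(
            np.zeros(s.out_classes, dtype=np.float32), requires_grad=True)

    @property
    def num_params(self) -> int:
        return sum(p.data.size for p in self.params.values())

    # ------------------------------------------------------------- forward

    def _apply_block(self, name, x, cout, final_relu=True):
        p = self.params
        g = _groups(self.spec, cout)
        h = nn.conv2d(x, p[f"{name}.0.w"], p[f"{name}.0.b"])
        h = nn.group_norm(h, p[f"{name}.0.g"], p[f"{name}.0.beta"], g)
        h = nn.relu(h)
        h = nn.conv2d(h, p[f"{name}.1.w"], p[f"{name}.1.b"])
        h = nn.group_norm(h, p[f"{name}.1.g"], p[f"{name}.1.beta"], g)
        return nn.relu(h) if final_relu else h

    def forward_t(self, image: nn.Tensor, fa: nn.Tensor | None) -> nn.Tensor:
        """Per-pixel class probabilities as a graph tensor (N,H,W,2)."""
        s = self.spec
        N, H, W, _ = image.data.shape
        div = 2 ** (s.depth - 1)
        if H % div or W % div:
            raise ValueError(
                f"spatial dims ({H},{W}) must be divisible by {div}; pad the input")
        if s.fusion != "none":
            if fa is None:
                raise ValueError("this network requires an FA map input")
            if fa.data.shape[1:3] != image.data.shape[1:3]:
                raise ValueError("image and FA map are not spatially aligned")
        ch = s.channels()
        x = image
        if s.fusion == "channel":
            x = nn.concat_ch(image, fa)
        a = fa
        skips = []
        for i in range(s.depth):
            x = self._apply_block(f"enc{i}", x, ch[i])
            if s.fusion == "multiple" or (s.fusion == "single" and i == 0):
                a = self._apply_block(f"fa{i}", a, ch[i], final_relu=False)
                a = nn.shift(nn.tanh(a), 1.0)  # attention in (0, 2)
                f = nn.mul(x, a)
            else:
                f = x
            if i < s.depth - 1:
                skips.append(f)
                x = nn.maxpool2(f)
                if s.fusion == "multiple":
                    a = nn.maxpool2(a)
            else:
                h = f
        for i in range(s.depth - 2, -1, -1):
            h = nn.concat_ch(nn.upsample2(h), skips[i])
            h = self._apply_block(f"dec{i}", h, ch[i])
        logits = nn.conv1x1(h, self.params["head.w"], self.params["head.b"])
        return nn.softmax_ch(logits)

    def predict_proba(self, image: np.ndarray, fa: np.ndarray | None = None) -> np.ndarray:
        """Foreground probability map (H,W) for a single image, no gradients."""
        img_t = nn.Tensor(np.asarray(image, dtype=np.float32)[None, :, :, None])
        fa_t = None
        if self.spec.fusion != "none":
            if fa is None:
                fa = np.zeros((3,) + image.shape, dtype=np.float32)
            fa_t = nn.Tensor(np.moveaxis(
                np.asarray(fa, dtype=np.float32), 0, -1)[None])
        frozen = Predictor.__new__(Predictor)
        frozen.spec = self.spec
        frozen.params = {k: nn.Tensor(p.data) for k, p in self.params.items()}
        prob = frozen.forward_t(img_t, fa_t)
        return prob.data[0, ..., 1].astype(np.float32)

    def predict_mask(self, image: np.ndarray, fa: np.ndarray | None = None,
                     threshold: float = 0.5) -> np.ndarray:
        return self.predict_proba(image, fa) > threshold

    # ------------------------------------------------------------ weights

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, p in self.params.items():
            p.data = np.asarray(state[k], dtype=p.data.dtype).copy()

    def save(self, path) -> None:
        arrays = {k.replace(".", "__"): p.data for k, p in self.params.items()}
        meta = dict(asdict(self.spec), init_seed=self.init_seed, trained=self.trained)
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path) -> "Predictor":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            trained = meta.pop("trained")
            seed = meta.pop("init_seed")
            spec = NetworkSpec(**meta)
            pred = cls(spec, seed)
            for k in pred.params:
                pred.params[k].data = z[k.replace(".", "__")].copy()
        pred.trained = trained
        return pred


def build_network(spec: NetworkSpec, seed: int) -> Predictor:
    """Construct a freshly initialized predictor; same seed => same weights."""
    return Predictor(spec, seed)
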