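"""U-Net for mapping N repetition images to one corrected image.

A symmetric encoder-decoder with skip connections: each resolution level
applies two 3x3 convolutions with ReLU, levels are connected by 2x2 max
pooling on the way down and nearest-neighbour upsampling plus channel
concatenation on the way up; a final 1x1 convolution produces the single
output image.  Channel counts double per level from ``base_channels``.

The output is linear (in normalized intensity units); nonnegativity is
applied after de-normalization, see :mod:`liverdwi.nettrain`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Adam, Tensor, concat, conv2d, maxpool2, upsample2

__all__ = ["UNetSpec", "UNet", "build_unet"]


@dataclass(frozen=True)
class UNetSpec:
    """Architecture of the correction network.

    ``depth`` counts resolution levels (so ``depth - 1`` poolings);
    ``in_channels`` must equal the repetition count N of the input stacks.
    """

    in_channels: int = 12
    out_channels: int = 1
    depth: int = 4
    base_channels: int = 32

    def __post_init__(self) -> None:
        if self.in_channels < 1 or self.out_channels != 1:
            raise ValueError("in_channels >= 1 and out_channels == 1 required")
        if self.depth < 1 or self.base_channels < 1:
            raise ValueError("depth and base_channels must be >= 1")


class UNet:
    """Encoder-decoder network over the numpy autodiff engine."""

    def __init__(self, spec: UNetSpec, rng: np.random.Generator | int = 0):
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.spec = spec
        self.params: list[Tensor] = []
        self._enc: list[tuple] = []
        self._dec: list[tuple] = []

        chans = [spec.base_channels * 2**i for i in range(spec.depth)]
        c_in = spec.in_channels
        for c in chans:
            self._enc.append((self._conv_pair(c_in, c, rng)))
            c_in = c
        for i in range(spec.depth - 2, -1, -1):
            c_skip, c_up = chans[i], chans[i + 1]
            self._dec.append(self._conv_pair(c_up + c_skip, c_skip, rng))
        self._head = self._make_conv(chans[0], spec.out_channels, 1, rng)

    # -- parameter construction ----------------------------------------------
    def _make_conv(
        self, c_in: int, c_out: int, k: int, rng: np.random.Generator
    ) -> tuple[Tensor, Tensor]:
        fan_in = c_in * k * k
        w = Tensor(
            (rng.standard_normal((c_out, c_in, k, k)) * np.sqrt(2.0 / fan_in)).astype(
                np.float32
            )
        )
        b = Tensor(np.zeros(c_out, dtype=np.float32))
        self.params += [w, b]
        return w, b

    def _conv_pair(self, c_in: int, c_out: int, rng) -> tuple:
        return (self._make_conv(c_in, c_out, 3, rng), self._make_conv(c_out, c_out, 3, rng))

    # -- forward --------------------------------------------------------------
    def forward(self, x: np.ndarray | Tensor) -> Tensor:
        """(B, C, H, W) -> (B, 1, H, W) linear output."""
        t = x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))
        b, c, h, w = t.data.shape
        if c != self.spec.in_channels:
            raise ValueError(
                f"input has {c} channels, network expects {self.spec.in_channels}"
            )
        down = 2 ** (self.spec.depth - 1)
        if h % down or w % down:
            raise ValueError(
                f"spatial size {h}x{w} not divisible by {down} "
                f"(depth {self.spec.depth})"
            )

        skips = []
        for i, ((w1, b1), (w2, b2)) in enumerate(self._enc):
            t = conv2d(t, w1, b1).relu()
            t = conv2d(t, w2, b2).relu()
            if i < self.spec.depth - 1:
                skips.append(t)
                t = maxpool2(t)
        for ((w1, b1), (w2, b2)), skip in zip(self._dec, reversed(skips)):
            t = concat(upsample2(t), skip, axis=1)
            t = conv2d(t, w1, b1).relu()
            t = conv2d(t, w2, b2).relu()
        wh, bh = self._head
        return conv2d(t, wh, bh)

    __call__ = forward

    # -- utilities ------------------------------------------------------------
    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.params))

    def get_weights(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def set_weights(self, weights: list[np.ndarray]) -> None:
        if len(weights) != len(self.params):
            raise ValueError("weight list length mismatch")
        for p, w in zip(self.params, weights):
            if p.data.shape != w.shape:
                raise ValueError("weight shape mismatch")
            p.data = w.copy()

    def make_optimizer(
        self, lr: float, beta1: float = 0.9, beta2: float = 0.999
    ) -> Adam:
        return Adam(self.params, lr=lr, beta1=beta1, beta2=beta2)


def build_unet(spec: UNetSpec | None = None, seed: int = 0) -> UNet:
    """Construct a seeded U-Net from an architecture spec."""
    return UNet(spec if spec is not None else UNetSpec(), rng=seed)
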