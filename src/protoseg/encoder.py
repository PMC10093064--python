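"""Feature encoders behind a fixed output contract.

Every encoder maps a batch of 3-channel images with side divisible by 8 to a
dense feature grid of shape (batch, 256, side/8, side/8). The contract — not
any particular backbone — is what the rest of the pipeline depends on: the
masked-average-pooled prototype is a 256-vector and similarity maps live on
the /8 grid.

The default backbone is a compact 4-layer convolutional net (three stride-2
3x3 convolutions with ReLU, then a 1x1 projection to 256 channels), randomly
initialized with He fan-in scaling. It trains end-to-end on a CPU in minutes
and needs no downloaded weights. Deeper backbones can be registered under a
config key and plugged in without touching anything downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .autodiff import Tensor, conv2d

__all__ = ["FeatureMap", "CompactEncoder", "build_encoder", "ENCODER_REGISTRY"]

FEATURE_CHANNELS = 256
DOWNSAMPLE = 8


@dataclass
class FeatureMap:
    """Encoded batch: (batch, 256, H/8, W/8) activations with a split index
    separating support features from query features."""

    data: Tensor
    n_support: int

    @property
    def support(self) -> Tensor:
        return self.data[: self.n_support]

    @property
    def query(self) -> Tensor:
        return self.data[self.n_support :]


class CompactEncoder:
    """Small randomly-initialized convolutional encoder (256 ch, stride 8)."""

    #: (out_ch, in_ch, kernel, stride, pad)
    _LAYERS = (
        (16, 3, 3, 2, 1),
        (32, 16, 3, 2, 1),
        (64, 32, 3, 2, 1),
        (256, 64, 1, 1, 0),
    )

    def __init__(self, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.params: dict[str, Tensor] = {}
        for li, (oc, ic, k, _, _) in enumerate(self._LAYERS):
            fan_in = ic * k * k
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(oc, ic, k, k))
            self.params[f"w{li}"] = Tensor(w, requires_grad=True)
            self.params[f"b{li}"] = Tensor(np.zeros(oc), requires_grad=True)

    def __call__(self, batch: Tensor) -> Tensor:
        x = batch
        last = len(self._LAYERS) - 1
        for li, (_, _, _, stride, pad) in enumerate(self._LAYERS):
            x = conv2d(x, self.params[f"w{li}"], self.params[f"b{li}"], stride=stride, pad=pad)
            if li != last:
                x = x.relu()
        return x

    # ---- weight checkpointing ---------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.asarray(state[k], dtype=np.float64)

    def save(self, path: str | Path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path: str | Path) -> "CompactEncoder":
        enc = cls()
        with np.load(path) as st:
            enc.load_state_dict(dict(st))
        return enc


ENCODER_REGISTRY = {"compact": CompactEncoder}


def build_encoder(name: str = "compact", seed: int = 0):
    try:
        return ENCODER_REGISTRY[name](seed=seed)
    except KeyError:
        raise ValueError(f"unknown encoder {name!r}; available: {sorted(ENCODER_REGISTRY)}")


def encode(batch: np.ndarray | Tensor, encoder, n_support: int | None = None) -> FeatureMap:
    """Run ``encoder`` on a batch, enforcing the (256-channel, /8) contract.

    ``batch`` is (B, 3, H, W) with H and W divisible by 8; the returned
    FeatureMap is (B, 256, H/8, W/8). ``n_support`` records where the support
    rows end and the query rows begin.
    """
    x = batch if isinstance(batch, Tensor) else Tensor(np.asarray(batch, dtype=np.float64))
    b, c, h, w = x.data.shape
    if c != 3:
        raise ValueError(f"encoder expects 3-channel input, got {c}")
    if h % DOWNSAMPLE or w % DOWNSAMPLE:
        raise ValueError(f"image side must be divisible by {DOWNSAMPLE}, got {(h, w)}")
    out = encoder(x)
    expected = (b, FEATURE_CHANNELS, h // DOWNSAMPLE, w // DOWNSAMPLE)
    if out.data.shape != expected:
        raise RuntimeError(f"encoder violated contract: {out.data.shape} != {expected}")
    return FeatureMap(data=out, n_support=b if n_support is None else n_support)
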