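"""SI-Net and baseline 2D U-Net architectures.

SI-Net is an encoder-decoder in which the encoder ("left side") runs 3D
convolutions over a depth-3 stack — the current image, the current contour
and the next adjacent image — to learn volumetric features, and the
decoder ("right side") runs 2D operations to localize the contour on the
next image.  The depth axis is kept at 3 throughout the encoder by
zero-padded 3×3×3 convolutions while in-plane resolution halves between
levels (1×2×2 max pooling); each skip connection collapses depth with a
3×1×1 max pooling and a channel-halving 1×1 convolution before it is
concatenated into the decoder.  At the bottom the depth axis is folded
into channels (the "reshape layer") and a 1×1 convolution restores the
level's channel count.  The head is a 1×1 convolution with a sigmoid, so
the output is a per-pixel probability of the contour on the next image.

The baseline U-Net is the standard 2D contracting/expanding architecture
with the same level and channel configuration, taking a single image.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .exceptions import ValidationError
from .nn import (
    BatchNorm,
    Conv2d,
    Conv3d,
    ConvTranspose2d,
    DepthCollapsePool,
    InPlanePool3d,
    Layer,
    MaxPool2d,
    Param,
    ReLU,
)

__all__ = [
    "NetworkConfig",
    "SInetInput",
    "SINet",
    "UNet2D",
    "build_sinet",
    "build_unet",
    "predict_slice",
    "save_weights",
    "load_weights",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters shared by SI-Net and the U-Net.

    in_plane_size : side length of the square input, divisible by 2**levels
        (512 at clinical scale; tests use 64).
    levels : number of encoder levels before the bottom block.
    base_channels : channels at the first level, doubling per level.
    batch_norm : insert batch normalization after every ReLU.
    """

    in_plane_size: int = 512
    levels: int = 4
    base_channels: int = 32
    batch_norm: bool = True

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValidationError(f"levels must be >= 2, got {self.levels}")
        if self.in_plane_size % (2**self.levels) != 0:
            raise ValidationError(
                f"in_plane_size {self.in_plane_size} not divisible by 2^levels = {2**self.levels}"
            )
        if self.base_channels < 1:
            raise ValidationError("base_channels must be >= 1")


@dataclass
class SInetInput:
    """The SI-Net unit of computation: (current image, current contour,
    next image), stacked along a depth axis of extent 3 in that order."""

    current_image: np.ndarray
    current_mask: np.ndarray
    next_image: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.current_image.shape, self.current_mask.shape, self.next_image.shape}
        if len(shapes) != 1 or self.current_image.ndim != 2:
            raise ValidationError(f"the three input planes must share one 2D shape, got {shapes}")

    def to_array(self, dtype=np.float32) -> np.ndarray:
        """(1, 1, 3, H, W) array: batch 1, one feature channel, depth 3."""
        return np.stack(
            [self.current_image, self.current_mask, self.next_image], axis=0
        ).astype(dtype)[None, None]


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _ConvBlock(Layer):
    """Two (conv -> ReLU -> [BN]) stages; 2D or 3D by conv class."""

    def __init__(self, conv_cls, c_in: int, c_out: int, batch_norm: bool,
                 rng: np.random.Generator, dtype):
        self.stages: list[list[Layer]] = []
        for cin in (c_in, c_out):
            stage: list[Layer] = [conv_cls(cin, c_out, 3, rng=rng, dtype=dtype), ReLU()]
            if batch_norm:
                stage.append(BatchNorm(c_out, dtype=dtype))
            self.stages.append(stage)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for stage in self.stages:
            for layer in stage:
                x = layer.forward(x, train)
        return x

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for stage in reversed(self.stages):
            for layer in reversed(stage):
                gy = layer.backward(gy)
        return gy

    def sublayers(self) -> list[tuple[str, Layer]]:
        out = []
        for i, stage in enumerate(self.stages):
            for layer in stage:
                out.append((f"s{i}.{type(layer).__name__.lower()}", layer))
        return out


class _ModelBase:
    """Shared plumbing: parameter/state registry, save/load, predict."""

    arch: str
    config: NetworkConfig

    def _registry(self) -> list[tuple[str, Layer]]:
        raise NotImplementedError

    def params(self) -> dict[str, Param]:
        out: dict[str, Param] = {}
        for prefix, layer in self._registry():
            for name, p in layer.params():
                out[f"{prefix}.{name}"] = p
        return out

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All persistent arrays: trainable params plus BN running stats."""
        out = {k: p.data for k, p in self.params().items()}
        for prefix, layer in self._registry():
            for name, arr in layer.state().items():
                out[f"{prefix}.{name}"] = arr
        return out

    def set_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        own = self.state_arrays()
        missing = sorted(set(own) - set(arrays))
        extra = sorted(set(arrays) - set(own))
        mismatched = [k for k in own if k in arrays and own[k].shape != arrays[k].shape]
        if missing or extra or mismatched:
            raise ValidationError(
                f"weight file does not match the model: missing={missing}, "
                f"unexpected={extra}, shape-mismatched={mismatched}"
            )
        params = self.params()
        for prefix, layer in self._registry():
            for name, p in layer.params():
                p.data = arrays[f"{prefix}.{name}"].copy()
            for name in layer.state():
                setattr(layer, name, arrays[f"{prefix}.{name}"].copy())
        # re-sync Param objects that were replaced
        for k, p in params.items():
            p.grad = np.zeros_like(p.data)

    def zero_grad(self) -> None:
        for p in self.params().values():
            p.zero_grad()

    def zero_weights(self) -> None:
        """Set every trainable parameter to zero (analytic test helper)."""
        for p in self.params().values():
            p.data[...] = 0.0

    def snapshot(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.state_arrays().items()}

    def restore(self, snap: dict[str, np.ndarray]) -> None:
        self.set_state_arrays(snap)


class SINet(_ModelBase):
    """The sequential-iterative network: 3D encoder, 2D decoder."""

    arch = "sinet"

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        L, B, bn = config.levels, config.base_channels, config.batch_norm
        enc_ch = [B * 2**l for l in range(L)]
        bot_ch = B * 2**L

        self.enc = [
            _ConvBlock(Conv3d, (1 if l == 0 else enc_ch[l - 1]), enc_ch[l], bn, rng, dtype)
            for l in range(L)
        ]
        self.depth_pools = [DepthCollapsePool() for _ in range(L)]
        self.squeeze = [Conv2d(enc_ch[l], max(1, enc_ch[l] // 2), 1, rng=rng, dtype=dtype)
                        for l in range(L)]
        self.plane_pools = [InPlanePool3d() for _ in range(L)]
        self.bottom = _ConvBlock(Conv3d, enc_ch[-1], bot_ch, bn, rng, dtype)
        self.bottom_squeeze = Conv2d(3 * bot_ch, bot_ch, 1, rng=rng, dtype=dtype)
        self.up = []
        self.dec = []
        for l in reversed(range(L)):
            c_in = bot_ch if l == L - 1 else enc_ch[l + 1]
            c_skip = max(1, enc_ch[l] // 2)
            self.up.append(ConvTranspose2d(c_in, c_skip, rng=rng, dtype=dtype))
            self.dec.append(_ConvBlock(Conv2d, 2 * c_skip, enc_ch[l], bn, rng, dtype))
        self.head = Conv2d(enc_ch[0], 1, 1, rng=rng, dtype=dtype)

    def _registry(self) -> list[tuple[str, Layer]]:
        reg: list[tuple[str, Layer]] = []
        for l, block in enumerate(self.enc):
            reg += [(f"enc{l}.{n}", lay) for n, lay in block.sublayers()]
            reg.append((f"squeeze{l}", self.squeeze[l]))
        reg += [(f"bottom.{n}", lay) for n, lay in self.bottom.sublayers()]
        reg.append(("bottom_squeeze", self.bottom_squeeze))
        for i, (u, d) in enumerate(zip(self.up, self.dec)):
            reg.append((f"up{i}", u))
            reg += [(f"dec{i}.{n}", lay) for n, lay in d.sublayers()]
        reg.append(("head", self.head))
        return reg

    def _check_input(self, x: np.ndarray) -> None:
        s = self.config.in_plane_size
        if x.ndim != 5 or x.shape[1] != 1 or x.shape[2] != 3 or x.shape[3:] != (s, s):
            raise ValidationError(
                f"SI-Net expects input (N, 1, 3, {s}, {s}), got {x.shape}"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 1, 3, H, W) -> probability maps (N, 1, H, W)."""
        self._check_input(x)
        x = x.astype(self.dtype, copy=False)
        skips = []
        h = x
        for l in range(self.config.levels):
            h = self.enc[l].forward(h, train)
            s = self.depth_pools[l].forward(h)
            s = self.squeeze[l].forward(s, train)
            skips.append(s)
            h = self.plane_pools[l].forward(h)
        h = self.bottom.forward(h, train)
        n, c, d, hh, ww = h.shape
        h = h.reshape(n, c * d, hh, ww)  # fold depth into channels
        h = self.bottom_squeeze.forward(h, train)
        for i, l in enumerate(reversed(range(self.config.levels))):
            h = self.up[i].forward(h, train)
            h = np.concatenate([h, skips[l]], axis=1)
            h = self.dec[i].forward(h, train)
        z = self.head.forward(h, train)
        self._z = z
        y = _sigmoid(z)
        self._y = y
        return y

    def backward(self, gy: np.ndarray) -> None:
        """Accumulate parameter gradients given dLoss/dOutput."""
        g = gy * self._y * (1.0 - self._y)  # through the sigmoid
        g = self.head.backward(g)
        skip_grads: dict[int, np.ndarray] = {}
        for i in reversed(range(self.config.levels)):
            l = self.config.levels - 1 - i
            g = self.dec[i].backward(g)
            half = g.shape[1] // 2
            g_up, g_skip = g[:, :half], g[:, half:]
            skip_grads[l] = g_skip
            g = self.up[i].backward(g_up)
        g = self.bottom_squeeze.backward(g)
        n, c3, hh, ww = g.shape
        g = g.reshape(n, c3 // 3, 3, hh, ww)
        g = self.bottom.backward(g)
        for l in reversed(range(self.config.levels)):
            g = self.plane_pools[l].backward(g)
            gs = self.squeeze[l].backward(skip_grads[l])
            g = g + self.depth_pools[l].backward(gs)
            g = self.enc[l].backward(g)

    def predict(self, inp: SInetInput) -> np.ndarray:
        """Single-sample inference: probability map (H, W)."""
        y = self.forward(inp.to_array(self.dtype), train=False)
        return y[0, 0]


class UNet2D(_ModelBase):
    """Standard 2D U-Net baseline: one image channel in, sigmoid map out."""

    arch = "unet"

    def __init__(self, config: NetworkConfig, seed: int = 0, dtype=np.float32):
        self.config = config
        self.dtype = dtype
        rng = np.random.default_rng(seed)
        L, B, bn = config.levels, config.base_channels, config.batch_norm
        enc_ch = [B * 2**l for l in range(L)]
        bot_ch = B * 2**L

        self.enc = [
            _ConvBlock(Conv2d, (1 if l == 0 else enc_ch[l - 1]), enc_ch[l], bn, rng, dtype)
            for l in range(L)
        ]
        self.pools = [MaxPool2d() for _ in range(L)]
        self.bottom = _ConvBlock(Conv2d, enc_ch[-1], bot_ch, bn, rng, dtype)
        self.up = []
        self.dec = []
        for l in reversed(range(L)):
            c_in = bot_ch if l == L - 1 else enc_ch[l + 1]
            self.up.append(ConvTranspose2d(c_in, enc_ch[l], rng=rng, dtype=dtype))
            self.dec.append(_ConvBlock(Conv2d, 2 * enc_ch[l], enc_ch[l], bn, rng, dtype))
        self.head = Conv2d(enc_ch[0], 1, 1, rng=rng, dtype=dtype)

    def _registry(self) -> list[tuple[str, Layer]]:
        reg: list[tuple[str, Layer]] = []
        for l, block in enumerate(self.enc):
            reg += [(f"enc{l}.{n}", lay) for n, lay in block.sublayers()]
        reg += [(f"bottom.{n}", lay) for n, lay in self.bottom.sublayers()]
        for i, (u, d) in enumerate(zip(self.up, self.dec)):
            reg.append((f"up{i}", u))
            reg += [(f"dec{i}.{n}", lay) for n, lay in d.sublayers()]
        reg.append(("head", self.head))
        return reg

    def _check_input(self, x: np.ndarray) -> None:
        s = self.config.in_plane_size
        if x.ndim != 4 or x.shape[1] != 1 or x.shape[2:] != (s, s):
            raise ValidationError(f"U-Net expects input (N, 1, {s}, {s}), got {x.shape}")

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._check_input(x)
        x = x.astype(self.dtype, copy=False)
        skips = []
        h = x
        for l in range(self.config.levels):
            h = self.enc[l].forward(h, train)
            skips.append(h)
            h = self.pools[l].forward(h)
        h = self.bottom.forward(h, train)
        for i, l in enumerate(reversed(range(self.config.levels))):
            h = self.up[i].forward(h, train)
            h = np.concatenate([h, skips[l]], axis=1)
            h = self.dec[i].forward(h, train)
        z = self.head.forward(h, train)
        y = _sigmoid(z)
        self._y = y
        return y

    def backward(self, gy: np.ndarray) -> None:
        g = gy * self._y * (1.0 - self._y)
        g = self.head.backward(g)
        skip_grads: dict[int, np.ndarray] = {}
        for i in reversed(range(self.config.levels)):
            l = self.config.levels - 1 - i
            g = self.dec[i].backward(g)
            half = g.shape[1] // 2
            g_up, g_skip = g[:, :half], g[:, half:]
            skip_grads[l] = g_skip
            g = self.up[i].backward(g_up)
        g = self.bottom.backward(g)
        for l in reversed(range(self.config.levels)):
            g = self.pools[l].backward(g)
            g = g + skip_grads[l]
            g = self.enc[l].backward(g)

    def predict(self, image: np.ndarray) -> np.ndarray:
        y = self.forward(np.asarray(image, dtype=self.dtype)[None, None], train=False)
        return y[0, 0]


def build_sinet(cfg: NetworkConfig, seed: int = 0, dtype=np.float32) -> SINet:
    """Construct an SI-Net with He-uniform initialized weights."""
    return SINet(cfg, seed=seed, dtype=dtype)


def build_unet(cfg: NetworkConfig, seed: int = 0, dtype=np.float32) -> UNet2D:
    """Construct the baseline 2D U-Net."""
    return UNet2D(cfg, seed=seed, dtype=dtype)


def predict_slice(model, inp) -> np.ndarray:
    """Run single-sample inference (inference-mode batch norm).

    ``inp`` is an :class:`SInetInput` for SI-Net or a 2D image for the
    U-Net; returns the (H, W) probability map.
    """
    return model.predict(inp)


def save_weights(model, path) -> None:
    """Save all parameter grids and running statistics to a single archive,
    with a JSON sidecar (``<path>.json``) recording the architecture and
    configuration."""
    path = Path(path)
    np.savez(path, **model.state_arrays())
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    sidecar = {"arch": model.arch, "config": asdict(model.config)}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def load_weights(path, cfg: NetworkConfig | None = None):
    """Load a model saved by :func:`save_weights`.

    If ``cfg`` is given it must match the sidecar configuration; mismatches
    and truncated/corrupt archives raise :class:`ValidationError` /
    :class:`IOError` respectively.
    """
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    if not path.exists():
        raise FileNotFoundError(f"no such weight file: {path}")
    sidecar_path = Path(str(path) + ".json")
    if not sidecar_path.exists():
        raise FileNotFoundError(f"missing config sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    stored_cfg = NetworkConfig(**sidecar["config"])
    if cfg is not None and cfg != stored_cfg:
        raise ValidationError(
            f"requested config {cfg} does not match stored config {stored_cfg}"
        )
    try:
        with np.load(path) as data:
            arrays = {k: data[k] for k in data.files}
    except (zipfile.BadZipFile, ValueError, EOFError, OSError) as e:
        raise IOError(f"corrupt or truncated weight file {path}: {e}") from e
    model = build_sinet(stored_cfg) if sidecar["arch"] == "sinet" else build_unet(stored_cfg)
    model.set_state_arrays(arrays)
    return model
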