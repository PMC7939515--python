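"""UNet-style fully convolutional encoder-decoder, implemented in numpy.

The network maps a single-channel hologram to a same-sized per-pixel
foreground probability map.  Encoder levels are (conv3x3 + ReLU) x2 blocks
separated by 2x2 max-pooling; the decoder mirrors them with 2x2 stride-2
transposed convolutions and skip concatenations; a final 1x1 convolution plus
sigmoid produces the probability map.  Convolutions are same-padded so input
and output sizes match, and because there are no fully connected layers one
trained model accepts any input whose sides are divisible by 2**(depth-1).

Forward and backward passes are written directly on BLAS matmuls.  Feature
maps are kept in channels-last (NHWC) layout: a same-padded 3x3 convolution
is then nine shifted-slice matmuls with no im2col materialization, which is
what makes single-CPU training of the desk-scale model practical.  Arithmetic
is float32 by default; float64 is available for gradient checking.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

__all__ = ["ModelConfig", "UNet", "build_model", "predict", "save_model", "load_model"]

_PROB_EPS = 1e-7  # keeps the returned probabilities strictly inside (0, 1)


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyper-parameters.

    ``depth`` is the number of resolution levels (5 at full scale, giving
    encoder widths 64/128/256/512/1024 with ``base_channels=64``); channel
    count doubles per level.  ``init_scheme="vgg_pretrained_encoder"`` loads a
    locally cached encoder initialization when present and silently falls back
    to He initialization otherwise, keeping the package download-free.
    """

    depth: int = 5
    base_channels: int = 64
    in_channels: int = 1
    out_channels: int = 1
    init_scheme: str = "he"
    #: expected foreground pixel fraction; the head bias starts at its logit
    #: so the initial output matches the class prior instead of 0.5, which
    #: avoids the early all-background plateau of imbalanced Dice+BCE training
    foreground_prior: float = 0.05

    def __post_init__(self) -> None:
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if self.init_scheme not in ("he", "vgg_pretrained_encoder"):
            raise ValueError(f"unknown init_scheme {self.init_scheme!r}")
        if not 0.0 < self.foreground_prior < 1.0:
            raise ValueError("foreground_prior must be in (0, 1)")

    @property
    def channel_widths(self) -> list[int]:
        return [self.base_channels * 2**i for i in range(self.depth)]

    @property
    def size_divisor(self) -> int:
        return 2 ** (self.depth - 1)


class _ConvReLU3x3:
    """Same-padded 3x3 convolution (stored as one (3, 3, Cin, Cout) kernel),
    optionally followed by ReLU.  He-initialized."""

    def __init__(self, cin, cout, rng, dtype, relu=True):
        std = np.sqrt(2.0 / (cin * 9))
        self.W = rng.normal(0.0, std, (3, 3, cin, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.relu = relu
        self._cache = None

    def forward(self, x, train):
        n, h, w, cin = x.shape
        cout = self.W.shape[3]
        xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (0, 0)))
        # nine shifted-slice matmuls; no im2col materialization
        y = np.empty((n, h, w, cout), dtype=x.dtype)
        y[...] = self.b
        for a in range(3):
            for b in range(3):
                y += xp[:, a : a + h, b : b + w, :] @ self.W[a, b]
        mask = None
        if self.relu:
            mask = y > 0
            np.multiply(y, mask, out=y)
        if train:
            self._cache = (xp, mask)
        return y

    def backward(self, dy):
        xp, mask = self._cache
        self._cache = None
        if mask is not None:
            dy = dy * mask
        n, h, w, cout = dy.shape
        cin = self.W.shape[2]
        dyr = dy.reshape(-1, cout)
        self.db = dyr.sum(axis=0)
        self.dW = np.empty_like(self.W)
        dxp = np.zeros_like(xp)
        buf = np.empty((n * h * w, cin), dtype=dy.dtype)
        buf4 = buf.reshape(n, h, w, cin)
        for a in range(3):
            for b in range(3):
                buf4[...] = xp[:, a : a + h, b : b + w, :]
                self.dW[a, b] = buf.T @ dyr
                dxp[:, a : a + h, b : b + w, :] += dy @ self.W[a, b].T
        return dxp[:, 1:-1, 1:-1, :]

    def params(self):
        return [("W", "dW"), ("b", "db")]


class _MaxPool2x2:
    def __init__(self):
        self._cache = None

    def forward(self, x, train):
        n, h, w, c = x.shape
        xr = x.reshape(n, h // 2, 2, w // 2, 2, c)
        xr = np.ascontiguousarray(xr.transpose(0, 1, 3, 2, 4, 5)).reshape(
            n, h // 2, w // 2, 4, c
        )
        idx = xr.argmax(axis=3)
        y = np.take_along_axis(xr, idx[:, :, :, None, :], axis=3)[:, :, :, 0, :]
        if train:
            self._cache = (idx, x.shape)
        return y

    def backward(self, dy):
        idx, (n, h, w, c) = self._cache
        self._cache = None
        dxr = np.zeros((n, h // 2, w // 2, 4, c), dtype=dy.dtype)
        np.put_along_axis(dxr, idx[:, :, :, None, :], dy[:, :, :, None, :], axis=3)
        dx = dxr.reshape(n, h // 2, w // 2, 2, 2, c).transpose(0, 1, 3, 2, 4, 5)
        return dx.reshape(n, h, w, c)

    def params(self):
        return []


class _UpConv2x2:
    """2x2 stride-2 transposed convolution (non-overlapping up-convolution)."""

    def __init__(self, cin, cout, rng, dtype):
        std = np.sqrt(2.0 / (cin * 4))
        self.W = rng.normal(0.0, std, (cin, 2, 2, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self._cache = None

    def forward(self, x, train):
        n, h, w, cin = x.shape
        cout = self.W.shape[3]
        t = x.reshape(-1, cin) @ self.W.reshape(cin, -1)  # (NHW, 2*2*Cout)
        t = t.reshape(n, h, w, 2, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        y = np.ascontiguousarray(t).reshape(n, 2 * h, 2 * w, cout)
        y += self.b
        if train:
            self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        self._cache = None
        n, h2, w2, cout = dy.shape
        h, w = h2 // 2, w2 // 2
        cin = self.W.shape[0]
        dt = dy.reshape(n, h, 2, w, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        dt = np.ascontiguousarray(dt).reshape(-1, 4 * cout)
        x2 = x.reshape(-1, cin)
        self.dW = (x2.T @ dt).reshape(self.W.shape)
        self.db = dy.sum(axis=(0, 1, 2))
        dx = dt @ self.W.reshape(cin, -1).T
        return dx.reshape(n, h, w, cin)

    def params(self):
        return [("W", "dW"), ("b", "db")]


class _Conv1x1:
    def __init__(self, cin, cout, rng, dtype):
        std = np.sqrt(2.0 / cin)
        self.W = rng.normal(0.0, std, (cin, cout)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self._cache = None

    def forward(self, x, train):
        y = x @ self.W
        y += self.b
        if train:
            self._cache = x
        return y

    def backward(self, dy):
        x = self._cache
        self._cache = None
        cin, cout = self.W.shape
        self.dW = x.reshape(-1, cin).T @ dy.reshape(-1, cout)
        self.db = dy.sum(axis=(0, 1, 2))
        return dy @ self.W.T

    def params(self):
        return [("W", "dW"), ("b", "db")]


class _DoubleConv:
    def __init__(self, cin, cout, rng, dtype):
        self.conv1 = _ConvReLU3x3(cin, cout, rng, dtype)
        self.conv2 = _ConvReLU3x3(cout, cout, rng, dtype)

    def forward(self, x, train):
        return self.conv2.forward(self.conv1.forward(x, train), train)

    def backward(self, dy):
        return self.conv1.backward(self.conv2.backward(dy))


class UNet:
    """Encoder-decoder FCN with sigmoid output; see module docstring.

    The public interface is channels-first (N, C, H, W); the channels-last
    internal layout is an implementation detail.
    """

    def __init__(self, cfg: ModelConfig, seed: int = 0, dtype=np.float32):
        self.cfg = cfg
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(seed)
        widths = cfg.channel_widths
        d = cfg.depth

        self.encoders = []
        cin = cfg.in_channels
        for i in range(d):
            self.encoders.append(_DoubleConv(cin, widths[i], rng, self.dtype))
            cin = widths[i]
        self.pools = [_MaxPool2x2() for _ in range(d - 1)]
        self.upconvs = []
        self.decoders = []
        for i in range(d - 2, -1, -1):  # decode levels d-2 .. 0
            self.upconvs.append(_UpConv2x2(widths[i + 1], widths[i], rng, self.dtype))
            self.decoders.append(_DoubleConv(2 * widths[i], widths[i], rng, self.dtype))
        self.head = _Conv1x1(widths[0], cfg.out_channels, rng, self.dtype)
        prior = cfg.foreground_prior
        self.head.b[:] = np.log(prior / (1.0 - prior))
        self._prob = None

        if cfg.init_scheme == "vgg_pretrained_encoder":
            self._try_load_encoder_cache()

    # -- initialization -----------------------------------------------------

    def _try_load_encoder_cache(self) -> None:
        """Load locally cached encoder weights if present; otherwise keep He."""
        path = Path(
            os.environ.get(
                "HOLOCOUNT_ENCODER_WEIGHTS",
                Path.home() / ".cache" / "holocount" / "encoder_init.npz",
            )
        )
        if not path.exists():
            return
        try:
            data = np.load(path)
        except OSError:
            return
        for i, enc in enumerate(self.encoders):
            for j, conv in enumerate((enc.conv1, enc.conv2)):
                for attr, key in (("W", f"enc{i}_conv{j}_W"), ("b", f"enc{i}_conv{j}_b")):
                    if key in data and data[key].shape == getattr(conv, attr).shape:
                        setattr(conv, attr, data[key].astype(self.dtype))

    # -- forward / backward -------------------------------------------------

    def _check_size(self, h: int, w: int) -> None:
        div = self.cfg.size_divisor
        if h % div or w % div:
            raise ValueError(
                f"input size {h}x{w} must be divisible by {div} "
                f"(= 2**(depth-1) for depth {self.cfg.depth})"
            )

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 1, H, W) -> (N, 1, H, W) probability maps strictly in (0, 1)."""
        x = np.asarray(x, dtype=self.dtype)
        self._check_size(x.shape[2], x.shape[3])
        x = np.ascontiguousarray(x.transpose(0, 2, 3, 1))  # to NHWC
        skips = []
        for i, enc in enumerate(self.encoders):
            x = enc.forward(x, train)
            if i < len(self.encoders) - 1:
                skips.append(x)
                x = self.pools[i].forward(x, train)
        self._skip_channels = [s.shape[3] for s in skips]
        for up, dec in zip(self.upconvs, self.decoders):
            x = up.forward(x, train)
            s = skips.pop()
            x = np.concatenate([s, x], axis=3)
            x = dec.forward(x, train)
        z = self.head.forward(x, train)
        prob = 1.0 / (1.0 + np.exp(-z))
        prob = np.clip(prob, _PROB_EPS, 1.0 - _PROB_EPS)
        if train:
            self._prob = prob
        return np.ascontiguousarray(prob.transpose(0, 3, 1, 2))

    def backward(self, dprob: np.ndarray) -> None:
        """Accumulate parameter gradients given dL/dprob (channels-first) for
        the last ``forward(..., train=True)`` batch."""
        prob = self._prob
        self._prob = None
        dprob = np.ascontiguousarray(np.asarray(dprob).transpose(0, 2, 3, 1))
        dz = (dprob * prob * (1.0 - prob)).astype(self.dtype)
        d = self.head.backward(dz)
        skip_grads = []
        # walk the decoder in reverse forward order
        for k in range(len(self.decoders) - 1, -1, -1):
            d = self.decoders[k].backward(d)
            cs = self._skip_channels[len(self.decoders) - 1 - k]
            ds, du = d[..., :cs], d[..., cs:]
            skip_grads.append(ds)
            d = self.upconvs[k].backward(np.ascontiguousarray(du))
        d = self.encoders[-1].backward(d)
        for i in range(len(self.encoders) - 2, -1, -1):
            d = self.pools[i].backward(d)
            d = d + skip_grads[i]  # skip_grads[m] is the level-m concat gradient
            d = self.encoders[i].backward(d)

    # -- parameter access ---------------------------------------------------

    def param_layers(self):
        layers = []
        for enc in self.encoders:
            layers += [enc.conv1, enc.conv2]
        for up, dec in zip(self.upconvs, self.decoders):
            layers += [up, dec.conv1, dec.conv2]
        layers.append(self.head)
        return layers

    def parameters(self) -> list[np.ndarray]:
        out = []
        for layer in self.param_layers():
            for attr, _ in layer.params():
                out.append(getattr(layer, attr))
        return out

    def set_parameters(self, values: list[np.ndarray]) -> None:
        it = iter(values)
        for layer in self.param_layers():
            for attr, _ in layer.params():
                setattr(layer, attr, next(it).astype(self.dtype))

    def n_parameters(self) -> int:
        return int(sum(p.size for p in self.parameters()))


def build_model(cfg: ModelConfig, seed: int = 0, dtype=np.float32) -> UNet:
    """Construct a UNet with seeded parameter initialization."""
    return UNet(cfg, seed=seed, dtype=dtype)


def predict(model: UNet, img: np.ndarray) -> np.ndarray:
    """Probability map for one normalized 2-D image (inference mode)."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("predict expects a single 2-D image")
    return model.forward(img[None, None], train=False)[0, 0]


def save_model(model: UNet, path: str | Path) -> None:
    """Checkpoint the model with its config (and, when the model was trained,
    the training-set normalization stats) embedded."""
    arrays = {f"p{i}": p for i, p in enumerate(model.parameters())}
    stats = getattr(model, "norm_stats", None)
    if stats is not None:
        arrays["norm_stats"] = np.array([stats.mean, stats.std], dtype=np.float64)
    np.savez(
        str(path),
        config=json.dumps(asdict(model.cfg)),
        dtype=str(model.dtype),
        **arrays,
    )


def load_model(path: str | Path) -> UNet:
    data = np.load(str(path), allow_pickle=False)
    cfg = ModelConfig(**json.loads(str(data["config"])))
    model = UNet(cfg, seed=0, dtype=np.dtype(str(data["dtype"])))
    n = len([k for k in data.files if k.startswith("p") and k != "norm_stats"])
    model.set_parameters([data[f"p{i}"] for i in range(n)])
    if "norm_stats" in data.files:
        from .data_pipeline import NormStats

        mean, std = data["norm_stats"]
        model.norm_stats = NormStats(mean=float(mean), std=float(std))
    return model
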