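"""A compact CPU implementation of the 2D U-Net and its optimizer.

Layers are plain numpy with explicit forward/backward passes (im2col
convolutions, batch normalization before ELU, 2x2 max pooling, nearest
upsampling with a channel-reducing 1x1 convolution, skip concatenation).
The loss is soft-Dice plus binary cross-entropy on the logits, and the
optimizer is Adam with L2 regularization added to the gradient. Everything
is deterministic given the initialization RNG and batch order, and every
backward pass is validated against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


# ---------------------------------------------------------------- layers


class Layer:
    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}


class Conv2d(Layer):
    """Same-padding 2D convolution with odd kernel size (or 1x1)."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 dtype=np.float32):
        if k % 2 == 0:
            raise ValueError("kernel size must be odd for same padding")
        fan_in = cin * k * k
        self.k = k
        self.cin, self.cout = cin, cout
        self.W = (rng.standard_normal((cout, fan_in)) * np.sqrt(2.0 / fan_in)).astype(dtype)
        self.b = np.zeros(cout, dtype=dtype)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)
        self._cols = None
        self._shape = None

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        k = self.k
        if k == 1:
            return x.transpose(0, 2, 3, 1).reshape(n * h * w, c)
        p = k // 2
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        win = sliding_window_view(xp, (k, k), axis=(2, 3))  # (n,c,h,w,k,k)
        return np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(
            n * h * w, c * k * k
        )

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        cols = self._im2col(x)
        out = cols @ self.W.T + self.b
        if train:
            self._cols = cols
            self._shape = (n, c, h, w)
        return out.reshape(n, h, w, self.cout).transpose(0, 3, 1, 2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, self.cout)
        self.dW = (dflat.T @ self._cols).astype(self.W.dtype)
        self.db = dflat.sum(axis=0).astype(self.b.dtype)
        self._cols = None
        # grad wrt input of a stride-1 same conv = same conv of dout with the
        # 180-degree-rotated kernel, input/output channels swapped
        k = self.k
        Wk = self.W.reshape(self.cout, self.cin, k, k)
        Wrot = Wk[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(
            self.cin, self.cout * k * k
        )
        tmp = Conv2d.__new__(Conv2d)
        tmp.k, tmp.cin, tmp.cout = k, self.cout, self.cin
        tmp.W, tmp.b = Wrot, np.zeros(self.cin, dtype=self.W.dtype)
        return tmp.forward(dout.astype(self.W.dtype), train=False)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}


class BatchNorm2d(Layer):
    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32):
        self.gamma = np.ones(c, dtype=dtype)
        self.beta = np.zeros(c, dtype=dtype)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(c, dtype=np.float64)
        self.running_var = np.ones(c, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        axes = (0, 2, 3)
        if train:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean = self.running_mean.astype(x.dtype)
            var = self.running_var.astype(x.dtype)
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std)
        return self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, inv_std = self._cache
        self._cache = None
        axes = (0, 2, 3)
        self.dgamma = (dout * xhat).sum(axis=axes).astype(self.gamma.dtype)
        self.dbeta = dout.sum(axis=axes).astype(self.beta.dtype)
        g = self.gamma[None, :, None, None] * inv_std[None, :, None, None]
        mean_d = dout.mean(axis=axes)[None, :, None, None]
        mean_dx = (dout * xhat).mean(axis=axes)[None, :, None, None]
        return g * (dout - mean_d - xhat * mean_dx)

    def params(self):
        return {"gamma": self.gamma, "beta": self.beta}

    def grads(self):
        return {"gamma": self.dgamma, "beta": self.dbeta}

    def state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}


class ELU(Layer):
    def __init__(self, alpha: float = 1.0):
        self.alpha = alpha
        self._y = None
        self._pos = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        pos = x > 0
        y = np.where(pos, x, self.alpha * np.expm1(np.minimum(x, 0)))
        if train:
            self._y, self._pos = y, pos
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = dout * np.where(self._pos, 1.0, self._y + self.alpha)
        self._y = self._pos = None
        return dx


class MaxPool2(Layer):
    """2x2 max pooling, stride 2; spatial dims must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c, h, w = x.shape
        r = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
        r = r.reshape(n, c, h // 2, w // 2, 4)
        idx = r.argmax(axis=-1)
        out = np.take_along_axis(r, idx[..., None], axis=-1)[..., 0]
        if train:
            self._idx = idx
            self._shape = (n, c, h, w)
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = self._shape
        dr = np.zeros((n, c, h // 2, w // 2, 4), dtype=dout.dtype)
        np.put_along_axis(dr, self._idx[..., None], dout[..., None], axis=-1)
        dr = dr.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5)
        return dr.reshape(n, c, h, w)


class UpsampleNearest2(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        return x.repeat(2, axis=2).repeat(2, axis=3)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, c, h, w = dout.shape
        return dout.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


class ConvBlock(Layer):
    """(Conv3x3 -> BN -> ELU) x 2, batch normalization before the activation."""

    def __init__(self, cin: int, cout: int, rng, dtype=np.float32):
        self.layers = [
            Conv2d(cin, cout, 3, rng, dtype), BatchNorm2d(cout, dtype=dtype), ELU(),
            Conv2d(cout, cout, 3, rng, dtype), BatchNorm2d(cout, dtype=dtype), ELU(),
        ]

    def forward(self, x, train=True):
        for layer in self.layers:
            x = layer.forward(x, train)
        return x

    def backward(self, dout):
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout


# ---------------------------------------------------------------- U-Net


@dataclass
class UNetSpec:
    """Architecture of the 5-channel-input 2D U-Net.

    ``in_channels`` equals ``2 * context_slices + 1`` of the patch engine;
    ``depth`` is the number of 2x2 poolings, so the patch size must be
    divisible by ``2 ** depth``.
    """

    in_channels: int = 5
    depth: int = 4
    base_filters: int = 64
    dtype: object = field(default=np.float32, repr=False)


class UNet:
    """Encoder-decoder with skip connections and a sigmoid pixel output."""

    def __init__(self, spec: UNetSpec, rng: np.random.Generator | None = None):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.spec = spec
        f, d, dt = spec.base_filters, spec.depth, spec.dtype
        self.enc = []
        cin = spec.in_channels
        for i in range(d):
            self.enc.append(ConvBlock(cin, f * 2**i, rng, dt))
            cin = f * 2**i
        self.pools = [MaxPool2() for _ in range(d)]
        self.bottleneck = ConvBlock(cin, f * 2**d, rng, dt)
        self.ups = [UpsampleNearest2() for _ in range(d)]
        self.up_convs = []   # 1x1 channel reduction after upsampling
        self.dec = []
        for i in reversed(range(d)):
            self.up_convs.append(Conv2d(f * 2 ** (i + 1), f * 2**i, 1, rng, dt))
            self.dec.append(ConvBlock(f * 2 ** (i + 1), f * 2**i, rng, dt))
        self.head = Conv2d(f, 1, 1, rng, dt)

    # -- plumbing

    def _modules(self):
        mods = {}
        for i, b in enumerate(self.enc):
            mods[f"enc{i}"] = b
        mods["bottleneck"] = self.bottleneck
        for i, (u, b) in enumerate(zip(self.up_convs, self.dec)):
            mods[f"upconv{i}"] = u
            mods[f"dec{i}"] = b
        mods["head"] = self.head
        return mods

    def _leaf_layers(self):
        for name, mod in self._modules().items():
            if isinstance(mod, ConvBlock):
                for j, layer in enumerate(mod.layers):
                    yield f"{name}.{j}", layer
            else:
                yield name, mod

    def params(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._leaf_layers():
            for k, v in layer.params().items():
                out[f"{name}.{k}"] = v
        return out

    def grads(self) -> dict[str, np.ndarray]:
        out = {}
        for name, layer in self._leaf_layers():
            for k, v in layer.grads().items():
                out[f"{name}.{k}"] = v
        return out

    def state_dict(self) -> dict[str, np.ndarray]:
        out = dict(self.params())
        for name, layer in self._leaf_layers():
            if isinstance(layer, BatchNorm2d):
                for k, v in layer.state().items():
                    out[f"{name}.{k}"] = v
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for name, layer in self._leaf_layers():
            for k in layer.params():
                layer.params()[k][...] = state[f"{name}.{k}"]
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = np.asarray(state[f"{name}.running_mean"], dtype=np.float64)
                layer.running_var = np.asarray(state[f"{name}.running_var"], dtype=np.float64)

    # -- forward / backward

    def forward_logits(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        x = np.ascontiguousarray(x, dtype=self.spec.dtype)
        if x.shape[1] != self.spec.in_channels:
            raise ValueError(f"expected {self.spec.in_channels} input channels")
        size = x.shape[2]
        if size % (2**self.spec.depth) or x.shape[3] % (2**self.spec.depth):
            raise ValueError(
                f"patch size {x.shape[2:]} not divisible by 2^{self.spec.depth}"
            )
        skips = []
        for block, pool in zip(self.enc, self.pools):
            x = block.forward(x, train)
            skips.append(x)
            x = pool.forward(x, train)
        x = self.bottleneck.forward(x, train)
        self._skip_channels = []
        for up, upconv, block, skip in zip(self.ups, self.up_convs, self.dec, reversed(skips)):
            x = up.forward(x, train)
            x = upconv.forward(x, train)
            self._skip_channels.append(skip.shape[1])
            x = block.forward(np.concatenate([skip, x], axis=1), train)
        return self.head.forward(x, train)[:, 0]

    def backward(self, dlogits: np.ndarray) -> None:
        d = self.head.backward(dlogits[:, None].astype(self.spec.dtype))
        dskips = []
        for upconv, up, block, cskip in zip(
            reversed(self.up_convs), reversed(self.ups), reversed(self.dec),
            reversed(self._skip_channels),
        ):
            d = block.backward(d)
            dskips.append(d[:, :cskip])
            d = up.backward(upconv.backward(d[:, cskip:]))
        d = self.bottleneck.backward(d)
        # dskips were collected shallow-to-deep; encoder unwinds deep-to-shallow
        for block, pool, dskip in zip(
            reversed(self.enc), reversed(self.pools), reversed(dskips)
        ):
            d = pool.backward(d) + dskip
            d = block.backward(d)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel probabilities in eval mode (running BN statistics)."""
        return sigmoid(self.forward_logits(x, train=False))


# ---------------------------------------------------------------- loss/optim


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def dice_bce_loss(
    logits: np.ndarray, targets: np.ndarray, mode: str = "dice_bce",
    eps: float = 1.0,
) -> tuple[float, np.ndarray]:
    """Soft-Dice + BCE loss and its gradient with respect to the logits.

    The Dice term is computed over the whole batch, which keeps it stable
    when many patches contain no foreground at all.
    """
    z = logits.astype(np.float64)
    t = targets.astype(np.float64)
    n = z.size
    p = sigmoid(z)
    loss, dz = 0.0, np.zeros_like(z)
    if mode in ("bce", "dice_bce"):
        bce = np.maximum(z, 0) - z * t + np.log1p(np.exp(-np.abs(z)))
        loss += bce.mean()
        dz += (p - t) / n
    if mode in ("dice", "dice_bce"):
        num = 2.0 * (p * t).sum() + eps
        den = p.sum() + t.sum() + eps
        loss += 1.0 - num / den
        dp = -(2.0 * t * den - num) / den**2
        dz += dp * p * (1.0 - p)
    if mode not in ("bce", "dice", "dice_bce"):
        raise ValueError(f"unknown loss mode {mode!r}")
    return float(loss), dz


class Adam:
    """Adam with L2 regularization added to the gradient (beta = weight decay)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-5):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k].astype(np.float64)
            if self.weight_decay and k.endswith(".W"):
                g = g + self.weight_decay * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            p -= (self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)).astype(p.dtype)


class ReduceLROnPlateau:
    """Halve the learning rate when the monitored metric stops improving.

    More than ``patience`` epochs without improvement trigger one reduction,
    i.e. with patience 2 and a never-improving metric the rate halves every
    3rd epoch.
    """

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 2,
                 min_lr: float = 0.0):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.min_lr = min_lr
        self.best = np.inf
        self.bad_epochs = 0

    def step(self, metric: float) -> float:
        if metric < self.best - 1e-12:
            self.best = metric
            self.bad_epochs = 0
        else:
            self.bad_epochs += 1
            if self.bad_epochs > self.patience:
                self.opt.lr = max(self.opt.lr * self.factor, self.min_lr)
                self.bad_epochs = 0
        return self.opt.lr
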