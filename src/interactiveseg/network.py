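"""A compact 3-D U-Net-style encoder-decoder, implemented directly on
numpy arrays with hand-written backpropagation and an Adam optimizer.

The network takes 2 input channels (normalized image + EGD map) and
produces 2-class logits on the same grid.  Architecture, parameter count
and initialization are pure functions of the configuration and seed, so
builds are bit-reproducible.  All tensors are channel-first
``(C, X, Y, Z)`` single-precision.

Design: ``depth`` resolution levels; each level applies two 3x3x3
convolutions (instance norm + leaky ReLU) with ``base_channels * 2**l``
features; 2x average pooling between levels; nearest-neighbor upsampling
and skip concatenation on the decoder path; a final 1x1x1 convolution to
the class logits.
"""

from __future__ import annotations

import numpy as np

_LEAK = 0.01
_EPS = 1e-5


# ---------------------------------------------------------------------------
# primitive layers (forward + backward)

def conv3(x: np.ndarray, W: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3x3 convolution, stride 1, zero padding 1. x: (Cin, X, Y, Z)."""
    X, Y, Z = x.shape[1:]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    out = np.broadcast_to(b[:, None, None, None], (W.shape[0], X, Y, Z)).copy()
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                out += np.tensordot(
                    W[:, :, dx, dy, dz],
                    xp[:, dx : dx + X, dy : dy + Y, dz : dz + Z],
                    axes=(1, 0),
                )
    return out


def conv3_backward(dout, x, W):
    X, Y, Z = x.shape[1:]
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1), (1, 1)))
    dxp = np.zeros_like(xp)
    dW = np.empty_like(W)
    for dx in range(3):
        for dy in range(3):
            for dz in range(3):
                patch = xp[:, dx : dx + X, dy : dy + Y, dz : dz + Z]
                dW[:, :, dx, dy, dz] = np.tensordot(
                    dout, patch, axes=([1, 2, 3], [1, 2, 3])
                )
                dxp[:, dx : dx + X, dy : dy + Y, dz : dz + Z] += np.tensordot(
                    W[:, :, dx, dy, dz].T, dout, axes=(1, 0)
                )
    db = dout.sum(axis=(1, 2, 3))
    return dxp[:, 1:-1, 1:-1, 1:-1], dW, db


def conv1(x, W, b):
    """1x1x1 convolution; W: (Cout, Cin)."""
    return np.tensordot(W, x, axes=(1, 0)) + b[:, None, None, None]


def conv1_backward(dout, x, W):
    dW = np.tensordot(dout, x, axes=([1, 2, 3], [1, 2, 3]))
    db = dout.sum(axis=(1, 2, 3))
    dx = np.tensordot(W.T, dout, axes=(1, 0))
    return dx, dW, db


def instance_norm(x, gamma, beta):
    mu = x.mean(axis=(1, 2, 3), keepdims=True)
    var = x.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + _EPS)
    xhat = (x - mu) * inv
    return gamma[:, None, None, None] * xhat + beta[:, None, None, None], (xhat, inv)


def instance_norm_backward(dout, cache, gamma):
    xhat, inv = cache
    dgamma = (dout * xhat).sum(axis=(1, 2, 3))
    dbeta = dout.sum(axis=(1, 2, 3))
    dxhat = dout * gamma[:, None, None, None]
    m1 = dxhat.mean(axis=(1, 2, 3), keepdims=True)
    m2 = (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
    dx = inv * (dxhat - m1 - xhat * m2)
    return dx, dgamma, dbeta


def leaky_relu(x):
    return np.where(x > 0, x, _LEAK * x)


def leaky_relu_backward(dout, x):
    return dout * np.where(x > 0, 1.0, _LEAK)


def avgpool2(x):
    C, X, Y, Z = x.shape
    return x.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2).mean(axis=(2, 4, 6))


def avgpool2_backward(dout):
    up = np.repeat(np.repeat(np.repeat(dout, 2, axis=1), 2, axis=2), 2, axis=3)
    return up / 8.0


def upsample2(x):
    return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)


def upsample2_backward(dout):
    C, X, Y, Z = dout.shape
    return dout.reshape(C, X // 2, 2, Y // 2, 2, Z // 2, 2).sum(axis=(2, 4, 6))


# ---------------------------------------------------------------------------


class ConfigurationError(ValueError):
    pass


class UNet3D:
    """Seeded, configuration-determined encoder-decoder network."""

    def __init__(
        self,
        depth: int = 3,
        base_channels: int = 8,
        in_channels: int = 2,
        out_channels: int = 2,
        norm: str = "instance",
        nonlinearity: str = "leaky_relu",
        seed: int = 0,
    ):
        if depth < 1:
            raise ConfigurationError("depth must be >= 1")
        if norm not in ("instance", "none"):
            raise ConfigurationError(f"unknown norm {norm!r}")
        if nonlinearity != "leaky_relu":
            raise ConfigurationError(f"unknown nonlinearity {nonlinearity!r}")
        self.depth = depth
        self.base_channels = base_channels
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.norm = norm
        self.params: dict[str, np.ndarray] = {}
        rng = np.random.default_rng(seed)
        chans = [base_channels * 2**l for l in range(depth)]
        self.channels = chans

        def add_conv3(name, cin, cout):
            fan_in = cin * 27
            self.params[f"{name}.W"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), size=(cout, cin, 3, 3, 3)
            ).astype(np.float32)
            self.params[f"{name}.b"] = np.zeros(cout, dtype=np.float32)
            if self.norm == "instance":
                self.params[f"{name}.g"] = np.ones(cout, dtype=np.float32)
                self.params[f"{name}.beta"] = np.zeros(cout, dtype=np.float32)

        for l in range(depth):
            cin = in_channels if l == 0 else chans[l - 1]
            add_conv3(f"enc{l}a", cin, chans[l])
            add_conv3(f"enc{l}b", chans[l], chans[l])
        for l in range(depth - 2, -1, -1):
            add_conv3(f"dec{l}a", chans[l + 1] + chans[l], chans[l])
            add_conv3(f"dec{l}b", chans[l], chans[l])
        self.params["head.W"] = rng.normal(
            0.0, np.sqrt(2.0 / chans[0]), size=(out_channels, chans[0])
        ).astype(np.float32)
        self.params["head.b"] = np.zeros(out_channels, dtype=np.float32)

    # -- plumbing ----------------------------------------------------------

    def num_parameters(self) -> int:
        return sum(p.size for p in self.params.values())

    def check_input_shape(self, shape) -> None:
        div = 2 ** (self.depth - 1)
        if any(s % div for s in shape):
            raise ConfigurationError(
                f"input shape {tuple(shape)} not divisible by {div}"
            )

    def _block(self, name, x, cache):
        """conv3 -> (instance norm) -> leaky relu."""
        y = conv3(x, self.params[f"{name}.W"], self.params[f"{name}.b"])
        if self.norm == "instance":
            z, nc = instance_norm(y, self.params[f"{name}.g"], self.params[f"{name}.beta"])
        else:
            z, nc = y, None
        out = leaky_relu(z)
        cache[name] = (x, nc, z)
        return out

    def _block_backward(self, name, dout, cache, grads):
        x, nc, z = cache[name]
        dz = leaky_relu_backward(dout, z)
        if self.norm == "instance":
            dy, dg, dbeta = instance_norm_backward(dz, nc, self.params[f"{name}.g"])
            grads[f"{name}.g"] = dg
            grads[f"{name}.beta"] = dbeta
        else:
            dy = dz
        dx, dW, db = conv3_backward(dy, x, self.params[f"{name}.W"])
        grads[f"{name}.W"] = dW
        grads[f"{name}.b"] = db
        return dx

    # -- forward / backward -------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Map (in_channels, X, Y, Z) to (out_channels, X, Y, Z) logits."""
        x = np.asarray(x, dtype=np.float32)
        self.check_input_shape(x.shape[1:])
        cache: dict = {}
        skips = []
        h = x
        for l in range(self.depth):
            h = self._block(f"enc{l}a", h, cache)
            h = self._block(f"enc{l}b", h, cache)
            if l < self.depth - 1:
                skips.append(h)
                h = avgpool2(h)
        for l in range(self.depth - 2, -1, -1):
            up = upsample2(h)
            skip = skips[l]
            h = np.concatenate([skip, up], axis=0)
            cache[f"cat{l}"] = skip.shape[0]
            h = self._block(f"dec{l}a", h, cache)
            h = self._block(f"dec{l}b", h, cache)
        cache["head_in"] = h
        logits = conv1(h, self.params["head.W"], self.params["head.b"])
        if want_cache:
            return logits, cache
        return logits

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        dh, dW, db = conv1_backward(
            dlogits.astype(np.float32), cache["head_in"], self.params["head.W"]
        )
        grads["head.W"] = dW
        grads["head.b"] = db
        dskips = [None] * (self.depth - 1)
        for l in range(self.depth - 1):
            dh = self._block_backward(f"dec{l}b", dh, cache, grads)
            dh = self._block_backward(f"dec{l}a", dh, cache, grads)
            nskip = cache[f"cat{l}"]
            dskips[l] = dh[:nskip]
            dh = upsample2_backward(dh[nskip:])
        for l in range(self.depth - 1, -1, -1):
            if l < self.depth - 1:
                dh = avgpool2_backward(dh)
                dh = dh + dskips[l]
            dh = self._block_backward(f"enc{l}b", dh, cache, grads)
            dh = self._block_backward(f"enc{l}a", dh, cache, grads)
        return grads

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        """Softmax class probabilities, shape (out_channels, X, Y, Z)."""
        return softmax(self.forward(x))

    # -- persistence ---------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32).reshape(
                self.params[k].shape
            )


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=0, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=0, keepdims=True)


def dice_ce_loss(
    logits: np.ndarray,
    target: np.ndarray,
    smooth: float = 1e-5,
    weights: tuple[float, float] = (1.0, 1.0),
):
    """Weighted soft Dice + cross-entropy (default equal weights), with
    the gradient w.r.t. the logits.

    ``target`` is a binary (X, Y, Z) array; the Dice term is computed on
    the foreground probability channel.
    """
    p = softmax(logits.astype(np.float64))
    t = np.asarray(target, dtype=np.float64)
    n = t.size
    p1 = p[1]

    w_dice, w_ce = weights
    ce = -(t * np.log(p1 + 1e-12) + (1 - t) * np.log(p[0] + 1e-12)).sum() / n
    inter = (p1 * t).sum()
    denom = p1.sum() + t.sum() + smooth
    dice = (2.0 * inter + smooth) / denom
    loss = w_dice * (1.0 - dice) + w_ce * ce

    # gradient of -dice w.r.t. p1, then CE gradient directly on logits
    ddice_dp1 = (2.0 * t * denom - (2.0 * inter + smooth)) / denom**2
    gp = np.zeros_like(p)
    gp[1] = -ddice_dp1
    # softmax jacobian: dl_k = p_k * (g_k - sum_j g_j p_j)
    dlog_dice = p * (gp - (gp * p).sum(axis=0, keepdims=True))
    onehot = np.stack([1.0 - t, t])
    dlog_ce = (p - onehot) / n
    grad = (w_dice * dlog_dice + w_ce * dlog_ce).astype(np.float32)
    return loss, float(1.0 - dice), float(ce), grad


class Adam:
    """Plain Adam; state keyed like the parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for k, g in grads.items():
            g = g.astype(np.float32)
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps
            )
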