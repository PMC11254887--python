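"""Minimal numpy CNN backend: 3x3/1x1 convolutions, max-pooling, nearest
upsampling, a U-Net with skip connections, soft-Dice loss and Adam.

Written against plain numpy so the segmentation stage runs in environments
without a deep-learning framework.  Arrays are NCHW float32; convolutions are
same-padded and implemented via im2col + GEMM.
"""

from __future__ import annotations

import json
import numpy as np

__all__ = ["UNet", "Adam", "soft_dice", "soft_dice_grad", "bce_logit_grad"]

_F32 = np.float32


def _im2col3(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N,H,W,C*9) patches for a same-padded 3x3 convolution."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    return win.transpose(0, 2, 3, 1, 4, 5).reshape(n, h, w, c * 9)


class Conv3x3:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (c_in * 9))  # He initialisation
        self.w = (rng.standard_normal((c_out, c_in, 3, 3)) * scale).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cols: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        cols = _im2col3(x)
        if train:
            self._cols = cols
        f = self.w.shape[0]
        y = cols @ self.w.reshape(f, -1).T + self.b
        return np.ascontiguousarray(y.transpose(0, 3, 1, 2))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        f, c_in = self.w.shape[:2]
        dyt = dy.transpose(0, 2, 3, 1)  # N,H,W,F
        self.dw = (
            dyt.reshape(-1, f).T @ self._cols.reshape(-1, c_in * 9)
        ).reshape(self.w.shape)
        self.db = dyt.sum(axis=(0, 1, 2))
        self._cols = None
        # dX = same-padded conv of dy with the flipped, transposed kernel
        w_t = np.ascontiguousarray(self.w.transpose(1, 0, 2, 3)[:, :, ::-1, ::-1])
        cols = _im2col3(dy)
        dx = cols @ w_t.reshape(c_in, -1).T
        return np.ascontiguousarray(dx.transpose(0, 3, 1, 2))

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Conv1x1:
    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / c_in)
        self.w = (rng.standard_normal((c_out, c_in)) * scale).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            self._x = x
        return np.einsum("fc,nchw->nfhw", self.w, x) + self.b[None, :, None, None]

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.dw = np.einsum("nfhw,nchw->fc", dy, self._x)
        self.db = dy.sum(axis=(0, 2, 3))
        self._x = None
        return np.einsum("fc,nfhw->nchw", self.w, dy)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class BatchNorm:
    """Per-channel batch normalisation with learnable scale/shift and running
    statistics for inference."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = np.ones(channels, dtype=_F32)
        self.beta = np.zeros(channels, dtype=_F32)
        self.dgamma = np.zeros_like(self.gamma)
        self.dbeta = np.zeros_like(self.beta)
        self.running_mean = np.zeros(channels, dtype=_F32)
        self.running_var = np.ones(channels, dtype=_F32)
        self.momentum = momentum
        self.eps = eps
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            # in-place so externally held buffer references stay valid
            self.running_mean *= self.momentum
            self.running_mean += ((1 - self.momentum) * mean).astype(_F32)
            self.running_var *= self.momentum
            self.running_var += ((1 - self.momentum) * var).astype(_F32)
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv_std[None, :, None, None]
        if train:
            self._cache = (xhat, inv_std, x.shape)
        return (self.gamma[None, :, None, None] * xhat + self.beta[None, :, None, None]).astype(_F32)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv_std, shape = self._cache
        self._cache = None
        n = shape[0] * shape[2] * shape[3]  # elements per channel
        self.dgamma = (dy * xhat).sum(axis=(0, 2, 3))
        self.dbeta = dy.sum(axis=(0, 2, 3))
        g = self.gamma[None, :, None, None] * inv_std[None, :, None, None]
        dy_sum = dy.sum(axis=(0, 2, 3), keepdims=True)
        corr = (dy * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (g * (dy - dy_sum / n - xhat * corr / n)).astype(_F32)

    def params(self):
        return [(self.gamma, self.dgamma), (self.beta, self.dbeta)]


class ReLU:
    def __init__(self):
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


def maxpool2(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    n, c, h, w = x.shape
    xr = x.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h // 2, w // 2, 4
    )
    idx = xr.argmax(axis=-1)
    y = np.take_along_axis(xr, idx[..., None], axis=-1)[..., 0]
    return y, idx


def maxpool2_backward(dy: np.ndarray, idx: np.ndarray, shape) -> np.ndarray:
    n, c, h, w = shape
    out = np.zeros((n, c, h // 2, w // 2, 4), dtype=dy.dtype)
    np.put_along_axis(out, idx[..., None], dy[..., None], axis=-1)
    return out.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        n, c, h, w
    )


def upsample2(x: np.ndarray) -> np.ndarray:
    return x.repeat(2, axis=2).repeat(2, axis=3)


def upsample2_backward(dy: np.ndarray) -> np.ndarray:
    n, c, h, w = dy.shape
    return dy.reshape(n, c, h // 2, 2, w // 2, 2).sum(axis=(3, 5))


def sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def soft_dice(pred: np.ndarray, truth: np.ndarray, eps: float = 1.0) -> float:
    """Soft Dice loss 1 - mean_channel (2*sum(p*t)+eps)/(sum(p)+sum(t)+eps).

    ``pred`` holds probabilities in [0,1].  Channel scores are averaged over
    every (sample, channel) pair; spatial axes are the last two.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {truth.shape}")
    inter = (pred * truth).sum(axis=(-2, -1))
    sums = pred.sum(axis=(-2, -1)) + truth.sum(axis=(-2, -1))
    dice_c = (2.0 * inter + eps) / (sums + eps)
    return float(1.0 - dice_c.mean())


def soft_dice_grad(pred: np.ndarray, truth: np.ndarray, eps: float = 1.0) -> np.ndarray:
    """d(loss)/d(pred) for the soft Dice loss above."""
    inter = (pred * truth).sum(axis=(-2, -1), keepdims=True)
    sums = pred.sum(axis=(-2, -1), keepdims=True) + truth.sum(axis=(-2, -1), keepdims=True)
    n_terms = np.prod(pred.shape[:-2])
    ddice = (2.0 * truth * (sums + eps) - (2.0 * inter + eps)) / (sums + eps) ** 2
    return (-ddice / n_terms).astype(pred.dtype)


def bce_logit_grad(pred: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """d(mean binary cross-entropy)/d(logits) = (p - t)/N.

    Used as a small stabiliser on top of the Dice gradient: unlike the Dice
    term it does not vanish when a sigmoid channel saturates, so collapsed
    channels can recover.
    """
    return ((pred - truth) / pred.size).astype(pred.dtype)


class _Block:
    """Two (3x3 conv -> batch-norm -> ReLU) stages."""

    def __init__(self, c_in, c_out, rng):
        self.c1 = Conv3x3(c_in, c_out, rng)
        self.n1 = BatchNorm(c_out)
        self.r1 = ReLU()
        self.c2 = Conv3x3(c_out, c_out, rng)
        self.n2 = BatchNorm(c_out)
        self.r2 = ReLU()

    def forward(self, x, train=True):
        h = self.r1.forward(self.n1.forward(self.c1.forward(x, train), train), train)
        return self.r2.forward(self.n2.forward(self.c2.forward(h, train), train), train)

    def backward(self, dy):
        d = self.c2.backward(self.n2.backward(self.r2.backward(dy)))
        return self.c1.backward(self.n1.backward(self.r1.backward(d)))

    def params(self):
        return self.c1.params() + self.n1.params() + self.c2.params() + self.n2.params()

    def buffers(self):
        return [
            self.n1.running_mean, self.n1.running_var,
            self.n2.running_mean, self.n2.running_var,
        ]


class UNet:
    """Encoder-decoder with skip connections and a sigmoid head.

    ``levels`` counts the encoder resolutions (>=2); channel width doubles per
    level starting from ``base``.
    """

    def __init__(self, in_ch: int = 4, out_ch: int = 4, base: int = 8, levels: int = 3, seed: int = 0):
        if levels < 2:
            raise ValueError("levels must be >= 2")
        rng = np.random.default_rng(seed)
        self.in_ch, self.out_ch, self.base, self.levels, self.seed = in_ch, out_ch, base, levels, seed
        widths = [base * 2**i for i in range(levels)]
        self.enc = []
        c = in_ch
        for wd in widths[:-1]:
            self.enc.append(_Block(c, wd, rng))
            c = wd
        self.bottleneck = _Block(c, widths[-1], rng)
        self.dec = []
        c = widths[-1]
        for wd in reversed(widths[:-1]):
            self.dec.append(_Block(c + wd, wd, rng))
            c = wd
        self.head = Conv1x1(c, out_ch, rng)
        self._cache: dict | None = None

    # -- descriptor / persistence ------------------------------------------
    def descriptor(self) -> dict:
        return {
            "in_ch": self.in_ch,
            "out_ch": self.out_ch,
            "base": self.base,
            "levels": self.levels,
            "seed": self.seed,
        }

    def _param_arrays(self) -> list[np.ndarray]:
        arrays = [p for p, _ in self.params()]
        arrays.extend(self.buffers())
        return arrays

    def buffers(self) -> list[np.ndarray]:
        out = []
        for b in self.enc:
            out += b.buffers()
        out += self.bottleneck.buffers()
        for b in self.dec:
            out += b.buffers()
        return out

    def save(self, path) -> None:
        arrays = {f"p{i}": a for i, a in enumerate(self._param_arrays())}
        np.savez_compressed(path, descriptor=json.dumps(self.descriptor()), **arrays)

    @classmethod
    def load(cls, path) -> "UNet":
        data = np.load(path, allow_pickle=False)
        desc = json.loads(str(data["descriptor"]))
        model = cls(**desc)
        for i, a in enumerate(model._param_arrays()):
            a[...] = data[f"p{i}"]
        return model

    def params(self):
        out = []
        for b in self.enc:
            out += b.params()
        out += self.bottleneck.params()
        for b in self.dec:
            out += b.params()
        out += self.head.params()
        return out

    # -- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        """Probability maps (N, out_ch, H, W) for input (N, in_ch, H, W)."""
        x = np.asarray(x, dtype=_F32)
        skips, pools = [], []
        h = x
        for block in self.enc:
            s = block.forward(h, train)
            skips.append(s)
            h, idx = maxpool2(s)
            pools.append((idx, s.shape))
        h = self.bottleneck.forward(h, train)
        for block, skip in zip(self.dec, reversed(skips)):
            h = np.concatenate([upsample2(h), skip], axis=1)
            h = block.forward(h, train)
        z = self.head.forward(h, train)
        p = sigmoid(z)
        if train:
            self._cache = {"pools": pools, "p": p, "n_skips": len(skips)}
        return p

    def backward(self, dloss_dp: np.ndarray, dloss_dz: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients given d(loss)/d(probabilities) and,
        optionally, an extra gradient taken directly w.r.t. the logits."""
        cache = self._cache
        p = cache["p"]
        dz = dloss_dp * p * (1.0 - p)
        if dloss_dz is not None:
            dz = dz + dloss_dz
        dh = self.head.backward(dz.astype(_F32))
        dskips = []
        for block in reversed(self.dec):
            d = block.backward(dh)
            # channel layout of the block input: [upsampled | skip]
            c_up = block.c1.w.shape[1] - self._skip_width(len(dskips))
            d_up, d_skip = d[:, :c_up], d[:, c_up:]
            dskips.append(d_skip)
            dh = upsample2_backward(d_up)
        dh = self.bottleneck.backward(dh)
        for block, (idx, shape), d_skip in zip(
            reversed(self.enc), reversed(cache["pools"]), reversed(dskips)
        ):
            d = maxpool2_backward(dh, idx, shape) + d_skip
            dh = block.backward(d)
        self._cache = None

    def _skip_width(self, reverse_index: int) -> int:
        # processing decoders last-to-first, the i-th processed block consumed
        # the skip from encoder level i (width base * 2**i)
        return self.base * 2**reverse_index


class Adam:
    def __init__(self, model: UNet, lr: float = 1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.model = model
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _ in model.params()]
        self.v = [np.zeros_like(p) for p, _ in model.params()]

    def step(self) -> None:
        self.t += 1
        for (p, g), m, v in zip(self.model.params(), self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
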