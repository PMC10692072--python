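"""A compact 3-D U-Net for volumetric segmentation, in pure numpy.

The network is the classic encoder–decoder with skip connections, scaled
down so that whole-volume training on 64³ phantoms runs on a single CPU:
three resolution levels, one 3×3×3 convolution + ReLU per level, 2×
average pooling, nearest-neighbour upsampling with a 1×1×1 channel
projection before each skip concatenation, and a final 1×1×1 convolution
producing a voxel-wise logit.  Convolutions are evaluated as im2col +
matrix product (float32) so both the forward and the hand-derived
backward pass run through BLAS.

Training uses Adam with L2 weight decay and the weighted composite loss

    loss = w_bce · BCE(logits, target) + w_dice · (1 − softDice(p, target))

where p = sigmoid(logits).  The Dice term dominates by default (1:10) to
counter the extreme foreground/background class imbalance of organoid
volumes.

Spatial shapes must be divisible by 4 (two pooling levels); callers pad
and crop (see :func:`pad_to_multiple`).
"""

from __future__ import annotations

import numpy as np

_KER = 3
_K3 = _KER**3


# ---------------------------------------------------------------------------
# primitive layers
# ---------------------------------------------------------------------------

def _im2col(x: np.ndarray) -> np.ndarray:
    """(C, D, H, W) -> (C·27, D·H·W) patch matrix with same zero padding.

    Row (c·27 + k) holds channel c shifted by kernel offset k, so a
    convolution is a single GEMM ``W.T @ cols``.  Rows are filled by
    contiguous-ish slice copies, which is what keeps the numpy
    implementation within memory bandwidth instead of gather-bound.
    """
    c, d, h, w = x.shape
    xp = np.pad(np.asarray(x, dtype=np.float32), ((0, 0), (1, 1), (1, 1), (1, 1)))
    n = d * h * w
    cols = np.empty((c * _K3, n), dtype=np.float32)
    k = 0
    for dz in range(_KER):
        for dy in range(_KER):
            for dx in range(_KER):
                block = xp[:, dz : dz + d, dy : dy + h, dx : dx + w]
                cols[k :: _K3, :] = block.reshape(c, n)
                k += 1
    return cols


def _conv3_forward(x, w, b):
    c_out = w.shape[1]
    _, d, h, wd = x.shape
    cols = _im2col(x)
    y = w.T @ cols + b[:, None]
    return y.reshape(c_out, d, h, wd), cols


def _conv3_backward(dy, cols, w, c_in):
    """Returns (dx, dw, db) for a same-padded stride-1 3×3×3 convolution."""
    c_out, d, h, wd = dy.shape
    dy_flat = np.ascontiguousarray(dy.reshape(c_out, -1), dtype=np.float32)
    dw = (dy_flat @ cols.T).T
    db = dy_flat.sum(axis=1)
    # gradient wrt input = convolution of dy with flipped kernels, channels swapped
    wr = w.reshape(c_in, _K3, c_out)
    w_back = np.ascontiguousarray(
        wr[:, ::-1, :].transpose(2, 1, 0).reshape(c_out * _K3, c_in)
    )
    cols_dy = _im2col(dy)
    dx = (w_back.T @ cols_dy).reshape(c_in, d, h, wd)
    return dx, dw, db


def _conv1_forward(x, w, b):
    c_in, d, h, wd = x.shape
    y = np.tensordot(w.T, x, axes=([1], [0])) + b[:, None, None, None]
    return y.astype(np.float32)


def _conv1_backward(dy, x, w):
    c_in = x.shape[0]
    c_out = dy.shape[0]
    dw = np.tensordot(x.reshape(c_in, -1), dy.reshape(c_out, -1), axes=([1], [1]))
    db = dy.reshape(c_out, -1).sum(axis=1)
    dx = np.tensordot(w, dy, axes=([1], [0]))
    return dx.astype(np.float32), dw, db


def _avgpool2(x):
    c, d, h, w = x.shape
    return x.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).mean(axis=(2, 4, 6))


def _avgpool2_backward(dy):
    up = np.repeat(np.repeat(np.repeat(dy, 2, axis=1), 2, axis=2), 2, axis=3)
    return (up / 8.0).astype(np.float32)


def _upsample2(x):
    return np.repeat(np.repeat(np.repeat(x, 2, axis=1), 2, axis=2), 2, axis=3)


def _upsample2_backward(dy):
    c, d, h, w = dy.shape
    return dy.reshape(c, d // 2, 2, h // 2, 2, w // 2, 2).sum(axis=(2, 4, 6))


def pad_to_multiple(vol: np.ndarray, multiple: int = 4):
    """Zero-pad a 3-D array so every axis is divisible by ``multiple``.

    Returns (padded, original_shape); use the shape to crop predictions back.
    """
    shape = vol.shape
    pads = [(0, (-s) % multiple) for s in shape]
    if any(p[1] for p in pads):
        vol = np.pad(vol, pads)
    return vol, shape


# ---------------------------------------------------------------------------
# the network
# ---------------------------------------------------------------------------

class UNet3D:
    """Three-level 3-D U-Net producing a voxel-wise logit map.

    Parameters
    ----------
    base_channels:
        Channels at the finest level; doubled per level (C, 2C, 4C).
    in_channels:
        Number of input channels (1 for a single MR contrast).
    seed:
        Seed for He-normal weight initialization.
    """

    def __init__(self, base_channels: int = 8, in_channels: int = 1, seed: int = 0):
        if base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        self.base_channels = int(base_channels)
        self.in_channels = int(in_channels)
        self.seed = int(seed)
        c = self.base_channels
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}

        def conv3(name, cin, cout):
            std = np.sqrt(2.0 / (cin * _K3))
            self.params[f"{name}_w"] = rng.normal(0, std, (cin * _K3, cout)).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

        def conv1(name, cin, cout):
            std = np.sqrt(2.0 / cin)
            self.params[f"{name}_w"] = rng.normal(0, std, (cin, cout)).astype(np.float32)
            self.params[f"{name}_b"] = np.zeros(cout, dtype=np.float32)

        conv3("enc0", self.in_channels, c)
        conv3("enc1", c, 2 * c)
        conv3("bott", 2 * c, 4 * c)
        conv1("up1", 4 * c, 2 * c)
        conv3("dec1", 4 * c, 2 * c)
        conv1("up0", 2 * c, c)
        conv3("dec0", 2 * c, c)
        conv1("out", c, 1)

    # -- forward / backward ------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """x: (C_in, D, H, W) float32, spatial dims divisible by 4."""
        x = np.ascontiguousarray(x, dtype=np.float32)
        p = self.params
        cache: dict[str, np.ndarray] = {}

        z0, cols0 = _conv3_forward(x, p["enc0_w"], p["enc0_b"])
        e0 = np.maximum(z0, 0)
        x1 = _avgpool2(e0)
        z1, cols1 = _conv3_forward(x1, p["enc1_w"], p["enc1_b"])
        e1 = np.maximum(z1, 0)
        x2 = _avgpool2(e1)
        zb, colsb = _conv3_forward(x2, p["bott_w"], p["bott_b"])
        b = np.maximum(zb, 0)

        u1 = _conv1_forward(_upsample2(b), p["up1_w"], p["up1_b"])
        cat1 = np.concatenate([u1, e1], axis=0)
        zd1, colsd1 = _conv3_forward(cat1, p["dec1_w"], p["dec1_b"])
        d1 = np.maximum(zd1, 0)

        u0 = _conv1_forward(_upsample2(d1), p["up0_w"], p["up0_b"])
        cat0 = np.concatenate([u0, e0], axis=0)
        zd0, colsd0 = _conv3_forward(cat0, p["dec0_w"], p["dec0_b"])
        d0 = np.maximum(zd0, 0)

        logits = _conv1_forward(d0, p["out_w"], p["out_b"])[0]

        if want_cache:
            cache.update(
                z0=z0, cols0=cols0, z1=z1, cols1=cols1, zb=zb, colsb=colsb,
                b_up=_upsample2(b), zd1=zd1, colsd1=colsd1, d1_up=_upsample2(d1),
                zd0=zd0, colsd0=colsd0, d0=d0, e0=e0, e1=e1,
            )
            return logits, cache
        return logits

    def backward(self, dlogits: np.ndarray, cache: dict) -> dict[str, np.ndarray]:
        p = self.params
        c = self.base_channels
        grads: dict[str, np.ndarray] = {}

        d0 = cache["d0"]
        dd0, grads["out_w"], grads["out_b"] = _conv1_backward(
            dlogits[None].astype(np.float32), d0, p["out_w"]
        )
        dzd0 = dd0 * (cache["zd0"] > 0)
        dcat0, grads["dec0_w"], grads["dec0_b"] = _conv3_backward(
            dzd0, cache["colsd0"], p["dec0_w"], 2 * c
        )
        du0, de0_skip = dcat0[:c], dcat0[c:]
        dd1_up, grads["up0_w"], grads["up0_b"] = _conv1_backward(
            du0, cache["d1_up"], p["up0_w"]
        )
        dd1 = _upsample2_backward(dd1_up)

        dzd1 = dd1 * (cache["zd1"] > 0)
        dcat1, grads["dec1_w"], grads["dec1_b"] = _conv3_backward(
            dzd1, cache["colsd1"], p["dec1_w"], 4 * c
        )
        du1, de1_skip = dcat1[: 2 * c], dcat1[2 * c :]
        db_up, grads["up1_w"], grads["up1_b"] = _conv1_backward(
            du1, cache["b_up"], p["up1_w"]
        )
        db = _upsample2_backward(db_up)

        dzb = db * (cache["zb"] > 0)
        dx2, grads["bott_w"], grads["bott_b"] = _conv3_backward(
            dzb, cache["colsb"], p["bott_w"], 2 * c
        )
        de1 = _avgpool2_backward(dx2) + de1_skip
        dz1 = de1 * (cache["z1"] > 0)
        dx1, grads["enc1_w"], grads["enc1_b"] = _conv3_backward(
            dz1, cache["cols1"], p["enc1_w"], c
        )
        de0 = _avgpool2_backward(dx1) + de0_skip
        dz0 = de0 * (cache["z0"] > 0)
        _, grads["enc0_w"], grads["enc0_b"] = _conv3_backward(
            dz0, cache["cols0"], p["enc0_w"], self.in_channels
        )
        return grads

    # -- inference ---------------------------------------------------------

    def predict_proba(self, vol: np.ndarray) -> np.ndarray:
        """Voxel-wise foreground probability for a 3-D volume (any shape)."""
        from scipy.special import expit

        padded, orig = pad_to_multiple(np.asarray(vol, dtype=np.float32))
        logits = self.forward(padded[None])
        probs = expit(logits.astype(np.float64))
        return probs[: orig[0], : orig[1], : orig[2]]

    # -- (de)serialization -------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.ascontiguousarray(state[k], dtype=np.float32)


# ---------------------------------------------------------------------------
# loss and optimizer
# ---------------------------------------------------------------------------

def bce_dice_loss(logits, target, bce_weight: float, dice_weight: float, eps: float = 1.0):
    """Composite loss and its gradient wrt the logits.

    Returns (loss, dloss/dlogits, soft_dice).  BCE is evaluated in the
    numerically stable log-sum-exp form; soft Dice uses sigmoid
    probabilities with additive smoothing ``eps``.
    """
    from scipy.special import expit

    z = logits.astype(np.float64)
    y = target.astype(np.float64)
    n = z.size
    p = expit(z)

    bce = float(np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z)))))
    dbce = (p - y) / n

    sp, sy, spy = p.sum(), y.sum(), (p * y).sum()
    denom = sp + sy + eps
    soft_dice = (2.0 * spy + eps) / denom
    dsoft_dp = (2.0 * y * denom - (2.0 * spy + eps)) / denom**2
    ddice = -dsoft_dp * p * (1.0 - p)

    loss = bce_weight * bce + dice_weight * (1.0 - soft_dice)
    dz = (bce_weight * dbce + dice_weight * ddice).astype(np.float32)
    return loss, dz, float(soft_dice)


class Adam:
    """Adam with decoupled-from-loss L2 weight decay added to the gradient."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 1e-7):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float32) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            g = grads[k].astype(np.float32)
            if self.weight_decay:
                g = g + self.weight_decay * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / b1t
            vhat = self.v[k] / b2t
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
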