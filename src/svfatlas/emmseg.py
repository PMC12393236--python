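"""Lightweight 3-D segmentation building blocks (EMM-Seg style).

Reference implementations, in plain NumPy, of the computational blocks of a
depthwise-separable Mamba-flavoured segmentation network: depthwise
convolution, the separable-vs-standard parameter count, a residual block
mixing features across positions through a softmax self-similarity matrix
(SSiM), the decoder softmax, trilinear skip addition, and the hybrid
cross-entropy + Dice loss. A small two-level network assembled from these
blocks, with hand-derived gradients, demonstrates end-to-end training at toy
scale (overfitting a single phantom).

Feature tensors are arrays of shape (H, W, D, C).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .fields import InvalidInputError

__all__ = [
    "dwconv",
    "param_count",
    "BlockParams",
    "rvm_block",
    "decoder_softmax",
    "skip_add",
    "hybrid_loss",
    "ToySegNet",
    "train_toy",
]


# ---------------------------------------------------------------------------
# functional blocks
# ---------------------------------------------------------------------------

def dwconv(X: np.ndarray, K: np.ndarray) -> np.ndarray:
    """Depthwise convolution: each channel is correlated with its own kernel,
    Y_c(i,j,k) = sum_{u,v,w} X_c(i+u, j+v, k+w) K_c(u,v,w), zero padded.

    X : (H, W, D, C); K : (C, k, k, k) with odd spatial size.
    """
    X = np.asarray(X, dtype=float)
    K = np.asarray(K, dtype=float)
    if X.ndim != 4 or K.ndim != 4:
        raise InvalidInputError(f"expected 4-D tensors, got {X.shape} and {K.shape}")
    if X.shape[-1] != K.shape[0]:
        raise InvalidInputError(
            f"channel mismatch: input has {X.shape[-1]} channels, {K.shape[0]} kernels")
    if any(s % 2 == 0 for s in K.shape[1:]):
        raise InvalidInputError("kernel spatial size must be odd")
    out = np.empty_like(X)
    for c in range(X.shape[-1]):
        out[..., c] = ndimage.correlate(X[..., c], K[c], mode="constant", cval=0.0)
    return out


def param_count(c_in: int, c_out: int, k: int, cubic: bool = False) -> tuple[int, int]:
    """Parameter counts of a depthwise-separable vs a standard convolution.

    p_sep = c_in * k^2 + c_in * c_out  (depthwise kernels + pointwise mixing)
    p_std = c_in * c_out * k^2

    ``cubic`` switches the spatial factor to k^3 for fully 3-D kernels.
    """
    if min(c_in, c_out, k) < 1:
        raise InvalidInputError("c_in, c_out and k must be positive integers")
    spatial = k ** 3 if cubic else k ** 2
    return c_in * spatial + c_in * c_out, c_in * c_out * spatial


@dataclass
class BlockParams:
    """Parameters of one residual self-similarity mixing (RVM) block over
    flattened positions x d features."""

    d: int
    W1: np.ndarray = None
    b1: np.ndarray = None
    gamma: np.ndarray = None   # layer-norm scale
    beta: np.ndarray = None    # layer-norm shift

    def __post_init__(self):
        if self.W1 is None:
            self.W1 = np.zeros((self.d, self.d))
        if self.b1 is None:
            self.b1 = np.zeros(self.d)
        if self.gamma is None:
            self.gamma = np.ones(self.d)
        if self.beta is None:
            self.beta = np.zeros(self.d)
        if self.W1.shape != (self.d, self.d) or self.b1.shape != (self.d,):
            raise InvalidInputError("BlockParams shapes inconsistent with d")


def _layernorm(F: np.ndarray, gamma: np.ndarray, beta: np.ndarray, eps: float = 1e-5):
    mu = F.mean(axis=-1, keepdims=True)
    var = F.var(axis=-1, keepdims=True)
    xhat = (F - mu) / np.sqrt(var + eps)
    return gamma * xhat + beta, (xhat, var)


def _softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def rvm_block(F: np.ndarray, params: BlockParams, return_parts: bool = False):
    """Residual self-similarity mixing block over positions.

    F' = Norm(F) + F W1^T + b1       (projection with layer norm)
    S  = rowwise softmax(F F^T / sqrt(d))
    out = F' + S F'                   (attention-weighted mixing, residual)

    F : (P, d) features at P spatial positions. Rows of S sum to 1.
    """
    F = np.asarray(F, dtype=float)
    if F.ndim != 2 or F.shape[1] != params.d:
        raise InvalidInputError(f"F must be (P, {params.d}), got {F.shape}")
    normed, _ = _layernorm(F, params.gamma, params.beta)
    Fp = normed + F @ params.W1.T + params.b1
    S = _softmax(F @ F.T / np.sqrt(params.d), axis=1)
    out = Fp + S @ Fp
    if return_parts:
        return out, Fp, S
    return out


def decoder_softmax(F_dec: np.ndarray) -> np.ndarray:
    """Voxelwise class probabilities from decoder logits (..., K), K >= 2."""
    F_dec = np.asarray(F_dec, dtype=float)
    if F_dec.shape[-1] < 2:
        raise InvalidInputError("decoder needs at least 2 class channels")
    return _softmax(F_dec, axis=-1)


def _upsample1d(x: np.ndarray, axis: int) -> np.ndarray:
    """Double the length along one axis with linear interpolation:
    out[2i] = x[i], out[2i+1] = (x[i] + x[i+1]) / 2 (edge clamped)."""
    x = np.moveaxis(x, axis, 0)
    n = x.shape[0]
    out = np.empty((2 * n,) + x.shape[1:], dtype=x.dtype)
    out[0::2] = x
    out[1:-1:2] = 0.5 * (x[:-1] + x[1:])
    out[-1] = x[-1]
    return np.moveaxis(out, 0, axis)


def _upsample1d_adjoint(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, 0)
    n = g.shape[0] // 2
    out = g[0::2].copy()
    mids = g[1:-1:2]
    out[:-1] += 0.5 * mids
    out[1:] += 0.5 * mids
    out[-1] += g[2 * n - 1]  # last odd output sample clamps to x[-1]
    return np.moveaxis(out, 0, axis)


def trilinear_upsample2(x: np.ndarray) -> np.ndarray:
    """2x trilinear upsampling of (H, W, D, C) along the spatial axes."""
    for ax in range(3):
        x = _upsample1d(x, ax)
    return x


def skip_add(F_low: np.ndarray, F_skip: np.ndarray) -> np.ndarray:
    """Skip connection: trilinearly upsample the low-resolution decoder
    features to the skip tensor's spatial size and add the encoder features."""
    F_low = np.asarray(F_low, dtype=float)
    F_skip = np.asarray(F_skip, dtype=float)
    if F_low.shape[-1] != F_skip.shape[-1]:
        raise InvalidInputError(
            f"channel mismatch: {F_low.shape[-1]} vs {F_skip.shape[-1]}")
    up = F_low
    while up.shape[:3] != F_skip.shape[:3]:
        if any(2 * a > b for a, b in zip(up.shape[:3], F_skip.shape[:3])):
            raise InvalidInputError(
                f"cannot upsample {F_low.shape[:3]} to {F_skip.shape[:3]} by doubling")
        up = trilinear_upsample2(up)
    return up + F_skip


def hybrid_loss(P: np.ndarray, Y: np.ndarray, eps: float = 1.0,
                clamp: float = 1e-7) -> float:
    """Hybrid segmentation loss L = L_CE + eps * L_Dice.

    L_CE is the mean voxelwise cross-entropy -log P(true class) (probability
    clamped at ``clamp``); L_Dice = 1 - mean over classes of the soft Dice
    2 sum(P_c Y_c) / (sum P_c + sum Y_c). ``eps`` balances voxel-level
    accuracy against shape consistency.
    """
    P = np.asarray(P, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if P.shape != Y.shape:
        raise InvalidInputError(f"shape mismatch: {P.shape} vs {Y.shape}")
    sums = P.sum(axis=-1)
    if not np.allclose(sums, 1.0, atol=1e-5):
        raise InvalidInputError("P rows must be normalized probabilities")
    ce = float(-(Y * np.log(np.maximum(P, clamp))).sum() / np.prod(P.shape[:-1]))
    axes = tuple(range(P.ndim - 1))
    inter = (P * Y).sum(axis=axes)
    denom = P.sum(axis=axes) + Y.sum(axis=axes)
    # smoothing keeps the score defined (=1) for classes absent from both
    soft_dice = (2.0 * inter + clamp) / (denom + clamp)
    return ce + eps * float(1.0 - soft_dice.mean())


# ---------------------------------------------------------------------------
# toy two-level network with hand-derived gradients
# ---------------------------------------------------------------------------

def _dwconv_backward(X: np.ndarray, K: np.ndarray, dY: np.ndarray):
    """Gradients of dwconv w.r.t. input and kernels."""
    dX = np.empty_like(X)
    for c in range(X.shape[-1]):
        dX[..., c] = ndimage.convolve(dY[..., c], K[c], mode="constant", cval=0.0)
    k = K.shape[1]
    r = k // 2
    dK = np.zeros_like(K)
    pad = [(r, r)] * 3
    for c in range(X.shape[-1]):
        Xp = np.pad(X[..., c], pad)
        H, W, D = X.shape[:3]
        for u in range(k):
            for v in range(k):
                for w in range(k):
                    dK[c, u, v, w] = (Xp[u:u + H, v:v + W, w:w + D] * dY[..., c]).sum()
    return dX, dK


def _avgpool2(x: np.ndarray) -> np.ndarray:
    H, W, D, C = x.shape
    return x.reshape(H // 2, 2, W // 2, 2, D // 2, 2, C).mean(axis=(1, 3, 5))


def _avgpool2_backward(g: np.ndarray, in_shape) -> np.ndarray:
    H, W, D, C = in_shape
    out = np.repeat(np.repeat(np.repeat(g, 2, axis=0), 2, axis=1), 2, axis=2)
    return out / 8.0


def _upsample2_adjoint(g: np.ndarray) -> np.ndarray:
    for ax in reversed(range(3)):
        g = _upsample1d_adjoint(g, ax)
    return g


class ToySegNet:
    """Two-level segmentation toy assembled from the blocks above.

    encoder:  pointwise(1->C) -> dwconv -> ReLU  (skip features)
              avgpool/2 -> pointwise(C->C) -> dwconv -> ReLU -> RVM block
    decoder:  trilinear upsample + skip -> pointwise(C->K) -> softmax

    Trained with Adam on the hybrid loss; gradients are derived by hand.
    """

    def __init__(self, channels: int = 16, n_classes: int = 3, kernel: int = 3,
                 seed: int = 0):
        rng = np.random.default_rng(seed)
        C, K = channels, kernel
        s = 0.3
        self.params = {
            "pw1": rng.normal(0, s, (1, C)), "pwb1": np.zeros(C),
            "dw1": rng.normal(0, s / K, (C, K, K, K)),
            "pw2": rng.normal(0, s / np.sqrt(C), (C, C)), "pwb2": np.zeros(C),
            "dw2": rng.normal(0, s / K, (C, K, K, K)),
            "W1": rng.normal(0, s / np.sqrt(C), (C, C)), "b1": np.zeros(C),
            "gamma": np.ones(C), "beta": np.zeros(C),
            "head": rng.normal(0, s / np.sqrt(C), (C, n_classes)),
            "headb": np.zeros(n_classes),
        }
        self.channels = C
        self.n_classes = n_classes

    def num_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))

    def forward(self, X: np.ndarray, cache: dict | None = None) -> np.ndarray:
        p = self.params
        if X.ndim == 3:
            X = X[..., None]
        h0 = X @ p["pw1"] + p["pwb1"]
        h1_pre = dwconv(h0, p["dw1"])
        skip = np.maximum(h1_pre, 0.0)
        pooled = _avgpool2(skip)
        h2a = pooled @ p["pw2"] + p["pwb2"]
        h2_pre = dwconv(h2a, p["dw2"])
        h2 = np.maximum(h2_pre, 0.0)
        P_pos = h2.reshape(-1, self.channels)
        blk = BlockParams(d=self.channels, W1=p["W1"], b1=p["b1"],
                          gamma=p["gamma"], beta=p["beta"])
        mixed, Fp, S = rvm_block(P_pos, blk, return_parts=True)
        low = mixed.reshape(h2.shape)
        up = skip_add(low, skip)
        logits = up @ p["head"] + p["headb"]
        probs = decoder_softmax(logits)
        if cache is not None:
            cache.update(X=X, h0=h0, h1_pre=h1_pre, skip=skip, pooled=pooled,
                         h2a=h2a, h2_pre=h2_pre, h2=h2, F=P_pos, Fp=Fp, S=S,
                         low=low, up=up, probs=probs)
        return probs

    # -- backward ----------------------------------------------------------

    def loss_and_grads(self, X: np.ndarray, Y: np.ndarray, eps: float = 1.0):
        cache: dict = {}
        P = self.forward(X, cache)
        loss = hybrid_loss(P, Y, eps=eps)
        p = self.params
        C = self.channels
        V = np.prod(P.shape[:-1])
        axes = tuple(range(P.ndim - 1))

        # d loss / d P  (CE uses clamped log; ignore clamp in gradient region)
        dP = -(Y / np.maximum(P, 1e-7)) / V
        clamp = 1e-7
        inter = (P * Y).sum(axis=axes)
        denom = P.sum(axis=axes) + Y.sum(axis=axes) + clamp
        Kc = P.shape[-1]
        # d(-mean soft dice)/dP_c with the smoothed score (2I+s)/(D+s)
        dP = dP + eps * (-(2.0 * Y * denom - (2.0 * inter + clamp)) / (denom ** 2)) / Kc

        # softmax backward
        dot = (dP * P).sum(axis=-1, keepdims=True)
        dlogits = P * (dP - dot)

        grads = {}
        up = cache["up"]
        grads["head"] = np.tensordot(up, dlogits, axes=([0, 1, 2], [0, 1, 2]))
        grads["headb"] = dlogits.sum(axis=(0, 1, 2))
        dup = dlogits @ p["head"].T

        dskip_from_add = dup
        dlow = _upsample2_adjoint(dup)

        dmixed = dlow.reshape(-1, C)
        F, Fp, S = cache["F"], cache["Fp"], cache["S"]
        # out = Fp + S Fp ; S = softmax(F F^T / sqrt(d))
        dFp = dmixed + S.T @ dmixed
        dS = dmixed @ Fp.T
        # softmax rows backward
        dZ = S * (dS - (dS * S).sum(axis=1, keepdims=True))
        scale = 1.0 / np.sqrt(C)
        dF_fromS = scale * (dZ @ F + dZ.T @ F)
        # Fp = LN(F) + F W1^T + b1
        grads["W1"] = dFp.T @ F
        grads["b1"] = dFp.sum(axis=0)
        dF_proj = dFp @ p["W1"]
        # layer norm backward
        eps_ln = 1e-5
        mu = F.mean(axis=-1, keepdims=True)
        var = F.var(axis=-1, keepdims=True)
        xhat = (F - mu) / np.sqrt(var + eps_ln)
        dxhat = dFp * p["gamma"]
        grads["gamma"] = (dFp * xhat).sum(axis=0)
        grads["beta"] = dFp.sum(axis=0)
        inv = 1.0 / np.sqrt(var + eps_ln)
        dF_ln = inv / C * (C * dxhat - dxhat.sum(axis=-1, keepdims=True)
                           - xhat * (dxhat * xhat).sum(axis=-1, keepdims=True))
        dF = dF_fromS + dF_proj + dF_ln
        dh2 = dF.reshape(cache["h2"].shape)

        dh2_pre = dh2 * (cache["h2_pre"] > 0)
        dh2a, grads["dw2"] = _dwconv_backward(cache["h2a"], p["dw2"], dh2_pre)
        grads["pw2"] = np.tensordot(cache["pooled"], dh2a, axes=([0, 1, 2], [0, 1, 2]))
        grads["pwb2"] = dh2a.sum(axis=(0, 1, 2))
        dpooled = dh2a @ p["pw2"].T
        dskip = _avgpool2_backward(dpooled, cache["skip"].shape) + dskip_from_add
        dh1_pre = dskip * (cache["h1_pre"] > 0)
        dh0, grads["dw1"] = _dwconv_backward(cache["h0"], p["dw1"], dh1_pre)
        grads["pw1"] = np.tensordot(cache["X"], dh0, axes=([0, 1, 2], [0, 1, 2]))
        grads["pwb1"] = dh0.sum(axis=(0, 1, 2))
        return loss, grads


def train_toy(net: ToySegNet, X: np.ndarray, Y: np.ndarray, steps: int = 500,
              lr: float = 2e-3, eps: float = 1.0) -> list:
    """Overfit the toy network on a single volume with Adam; returns the
    per-step hybrid-loss trace."""
    m = {k: np.zeros_like(v) for k, v in net.params.items()}
    s = {k: np.zeros_like(v) for k, v in net.params.items()}
    b1, b2, adam_eps = 0.9, 0.999, 1e-8
    trace = []
    for t in range(1, steps + 1):
        loss, grads = net.loss_and_grads(X, Y, eps=eps)
        trace.append(loss)
        for k in net.params:
            g = grads[k]
            m[k] = b1 * m[k] + (1 - b1) * g
            s[k] = b2 * s[k] + (1 - b2) * g * g
            mhat = m[k] / (1 - b1 ** t)
            shat = s[k] / (1 - b2 ** t)
            net.params[k] -= lr * mhat / (np.sqrt(shat) + adam_eps)
    return trace
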