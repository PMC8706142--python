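"""Minimal define-by-run autodiff for small convolutional segmentation nets.

Implements exactly the pieces the segmentation architectures need — 2-D
convolution (stride/dilation), ReLU, residual addition, channel
concatenation, adaptive average pooling, nearest/bilinear upsampling,
detach, softmax cross-entropy — with hand-written backward passes on numpy
arrays (NCHW, float32), plus the Adadelta optimiser.  Everything is
deterministic: no threading, no hidden RNG.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Var",
    "backward",
    "conv2d",
    "relu",
    "add",
    "concat",
    "adaptive_avg_pool",
    "upsample_nearest",
    "upsample_bilinear",
    "detach",
    "softmax_cross_entropy",
    "Adadelta",
    "he_init",
]


class Var:
    """A node in the computation graph: value, accumulated gradient, closure."""

    __slots__ = ("value", "grad", "parents", "bwd", "requires_grad")

    def __init__(self, value, parents=(), bwd=None, requires_grad=True):
        value = np.asarray(value, dtype=np.float32)
        if value.ndim and not value.flags["C_CONTIGUOUS"]:
            value = np.ascontiguousarray(value)
        self.value = value
        self.grad = None
        self.parents = parents
        self.bwd = bwd
        self.requires_grad = requires_grad

    @property
    def shape(self):
        return self.value.shape

    def accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g


def backward(root: Var) -> None:
    """Reverse-mode sweep from a scalar root."""
    topo: list[Var] = []
    seen: set[int] = set()
    stack = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            topo.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if id(p) not in seen:
                stack.append((p, False))
    root.grad = np.ones_like(root.value)
    for node in reversed(topo):
        if node.bwd is not None and node.grad is not None:
            node.bwd(node.grad)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


# --------------------------------------------------------------------------
# convolution

_IDX_CACHE: dict = {}


def _conv_indices(H, W, kh, kw, stride, dilation, pad):
    key = (H, W, kh, kw, stride, dilation, pad)
    hit = _IDX_CACHE.get(key)
    if hit is not None:
        return hit
    Ho = (H + 2 * pad - dilation * (kh - 1) - 1) // stride + 1
    Wo = (W + 2 * pad - dilation * (kw - 1) - 1) // stride + 1
    Wp = W + 2 * pad
    r0 = np.arange(Ho) * stride
    c0 = np.arange(Wo) * stride
    kr = np.arange(kh) * dilation
    kc = np.arange(kw) * dilation
    R = r0[:, None, None, None] + kr[None, None, :, None]  # Ho,1,kh,1
    C = c0[None, :, None, None] + kc[None, None, None, :]  # 1,Wo,1,kw
    flat = (R * Wp + C)  # Ho,Wo,kh,kw (broadcast)
    flat = np.broadcast_to(flat, (Ho, Wo, kh, kw)).reshape(Ho * Wo, kh * kw)
    flat = np.ascontiguousarray(flat.T)  # K, L
    _IDX_CACHE[key] = (Ho, Wo, flat)
    return Ho, Wo, flat


def conv2d(x: Var, w: Var, b: Var, stride: int = 1, dilation: int = 1) -> Var:
    """Same-padded 2-D convolution, NCHW; weights (Cout, Cin, kh, kw)."""
    N, C, H, W = x.value.shape
    Cout, Cin, kh, kw = w.value.shape
    assert Cin == C, f"channel mismatch {Cin} vs {C}"
    pad = dilation * (kh - 1) // 2
    Ho, Wo, flat = _conv_indices(H, W, kh, kw, stride, dilation, pad)
    K, L = flat.shape

    if pad:
        xp = np.zeros((N, C, H + 2 * pad, W + 2 * pad), dtype=np.float32)
        xp[:, :, pad : pad + H, pad : pad + W] = x.value
    else:
        xp = x.value
    xf = xp.reshape(N, C, -1)
    cols = xf[:, :, flat]  # N, C, K, L
    colsr = cols.reshape(N, C * K, L)
    W2 = w.value.reshape(Cout, C * K)
    out = np.matmul(W2, colsr) + b.value[:, None]  # N, Cout, L
    out = out.reshape(N, Cout, Ho, Wo)

    def bwd(g):
        gr = g.reshape(N, Cout, L)
        if w.requires_grad:
            dW2 = np.einsum("nol,nkl->ok", gr, colsr, optimize=True)
            w.accumulate(dW2.reshape(Cout, C, kh, kw))
            b.accumulate(gr.sum(axis=(0, 2)))
        if x.requires_grad:
            dcols = np.matmul(W2.T, gr)  # N, C*K, L
            buf = np.zeros((N * C, xp.shape[2] * xp.shape[3]), dtype=np.float32)
            idx = flat.reshape(-1)  # K*L
            np.add.at(
                buf,
                (np.arange(N * C)[:, None], idx[None, :]),
                dcols.reshape(N, C, K * L).reshape(N * C, K * L),
            )
            dxp = buf.reshape(N, C, xp.shape[2], xp.shape[3])
            dx = dxp[:, :, pad : pad + H, pad : pad + W] if pad else dxp
            x.accumulate(dx)

    return Var(out, parents=(x, w, b), bwd=bwd)


def relu(x: Var) -> Var:
    mask = x.value > 0

    def bwd(g):
        if x.requires_grad:
            x.accumulate(g * mask)

    return Var(x.value * mask, parents=(x,), bwd=bwd)


def add(a: Var, b: Var) -> Var:
    def bwd(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    return Var(a.value + b.value, parents=(a, b), bwd=bwd)


def concat(vars_: list[Var]) -> Var:
    sizes = [v.value.shape[1] for v in vars_]
    out = np.concatenate([v.value for v in vars_], axis=1)

    def bwd(g):
        o = 0
        for v, c in zip(vars_, sizes):
            if v.requires_grad:
                v.accumulate(g[:, o : o + c])
            o += c

    return Var(out, parents=tuple(vars_), bwd=bwd)


def detach(x: Var) -> Var:
    """Stop-gradient: forwards the value, blocks the backward path."""
    return Var(x.value, parents=(), bwd=None)


def adaptive_avg_pool(x: Var, out_hw: tuple[int, int]) -> Var:
    """Average pooling to a fixed output grid (contiguous bins)."""
    N, C, H, W = x.value.shape
    ph, pw = out_hw
    re = np.floor(np.arange(ph + 1) * H / ph).astype(int)
    ce = np.floor(np.arange(pw + 1) * W / pw).astype(int)
    out = np.empty((N, C, ph, pw), dtype=np.float32)
    for i in range(ph):
        for j in range(pw):
            out[:, :, i, j] = x.value[:, :, re[i] : re[i + 1], ce[j] : ce[j + 1]].mean(
                axis=(2, 3)
            )

    def bwd(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.value)
        for i in range(ph):
            for j in range(pw):
                n = (re[i + 1] - re[i]) * (ce[j + 1] - ce[j])
                dx[:, :, re[i] : re[i + 1], ce[j] : ce[j + 1]] += (
                    g[:, :, i : i + 1, j : j + 1] / n
                )
        x.accumulate(dx)

    return Var(out, parents=(x,), bwd=bwd)


def upsample_nearest(x: Var, out_hw: tuple[int, int]) -> Var:
    N, C, H, W = x.value.shape
    Ho, Wo = out_hw
    ri = np.floor(np.arange(Ho) * H / Ho).astype(int)
    ci = np.floor(np.arange(Wo) * W / Wo).astype(int)
    out = x.value[:, :, ri][:, :, :, ci]

    def bwd(g):
        if not x.requires_grad:
            return
        dx = np.zeros_like(x.value)
        # scatter-add by bincount over flattened target indices
        tgt = (ri[:, None] * W + ci[None, :]).reshape(-1)
        gf = g.reshape(N, C, -1)
        dxf = np.zeros((N, C, H * W), dtype=np.float32)
        np.add.at(dxf, (slice(None), slice(None), tgt), gf)
        x.accumulate(dxf.reshape(N, C, H, W))

    return Var(out, parents=(x,), bwd=bwd)


def upsample_bilinear(x: Var, out_hw: tuple[int, int]) -> Var:
    """Bilinear resize with align_corners=False semantics."""
    N, C, H, W = x.value.shape
    Ho, Wo = out_hw
    fy = (np.arange(Ho) + 0.5) * H / Ho - 0.5
    fx_ = (np.arange(Wo) + 0.5) * W / Wo - 0.5
    y0 = np.clip(np.floor(fy).astype(int), 0, H - 1)
    x0 = np.clip(np.floor(fx_).astype(int), 0, W - 1)
    y1 = np.clip(y0 + 1, 0, H - 1)
    x1 = np.clip(x0 + 1, 0, W - 1)
    wy = np.clip(fy - y0, 0.0, 1.0).astype(np.float32)
    wx = np.clip(fx_ - x0, 0.0, 1.0).astype(np.float32)

    v = x.value
    top = v[:, :, y0][:, :, :, x0] * (1 - wx) + v[:, :, y0][:, :, :, x1] * wx
    bot = v[:, :, y1][:, :, :, x0] * (1 - wx) + v[:, :, y1][:, :, :, x1] * wx
    out = top * (1 - wy)[None, None, :, None] + bot * wy[None, None, :, None]

    def bwd(g):
        if not x.requires_grad:
            return
        dxf = np.zeros((N, C, H * W), dtype=np.float32)
        for ys, wys in ((y0, 1 - wy), (y1, wy)):
            for xs, wxs in ((x0, 1 - wx), (x1, wx)):
                wgt = (wys[:, None] * wxs[None, :]).astype(np.float32)
                tgt = (ys[:, None] * W + xs[None, :]).reshape(-1)
                contrib = (g * wgt[None, None]).reshape(N, C, -1)
                np.add.at(dxf, (slice(None), slice(None), tgt), contrib)
        x.accumulate(dxf.reshape(N, C, H, W))

    return Var(out.astype(np.float32), parents=(x,), bwd=bwd)


def softmax_cross_entropy(logits: Var, labels: np.ndarray) -> tuple[Var, float]:
    """Mean per-pixel cross-entropy over NCHW logits and NHW integer labels.

    Returns the scalar loss node and the (detached) mean pixel accuracy.
    """
    N, C, H, W = logits.value.shape
    z = logits.value - logits.value.max(axis=1, keepdims=True)
    ez = np.exp(z)
    p = ez / ez.sum(axis=1, keepdims=True)
    lab = labels.astype(np.int64)
    n_pix = N * H * W
    idx_n, idx_h, idx_w = np.meshgrid(
        np.arange(N), np.arange(H), np.arange(W), indexing="ij"
    )
    picked = p[idx_n, lab, idx_h, idx_w]
    loss = float(-np.log(np.clip(picked, 1e-12, None)).mean())
    acc = float((logits.value.argmax(axis=1) == lab).mean())

    def bwd(g):
        if not logits.requires_grad:
            return
        d = p.copy()
        d[idx_n, lab, idx_h, idx_w] -= 1.0
        logits.accumulate(d * (g / n_pix))

    return Var(np.float32(loss), parents=(logits,), bwd=bwd), acc


class Adadelta:
    """Adadelta (per-parameter running averages of squared grad and update)."""

    def __init__(self, params: list[Var], rho: float = 0.95, eps: float = 1e-6, lr: float = 1.0):
        self.params = params
        self.rho = rho
        self.eps = eps
        self.lr = lr
        self._eg = [np.zeros_like(p.value) for p in params]
        self._ed = [np.zeros_like(p.value) for p in params]

    def step(self) -> None:
        for p, eg, ed in zip(self.params, self._eg, self._ed):
            if p.grad is None:
                continue
            g = p.grad
            eg *= self.rho
            eg += (1 - self.rho) * g * g
            upd = -np.sqrt(ed + self.eps) / np.sqrt(eg + self.eps) * g
            ed *= self.rho
            ed += (1 - self.rho) * upd * upd
            p.value += self.lr * upd

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
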