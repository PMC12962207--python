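"""Unrolled model-based reconstruction with a complex-valued ResNet denoiser.

The reconstruction alternates, for a fixed number of unrolls sharing one
set of weights, a proximal-gradient data-consistency step

    z_{t+1} = m_t - 2 alpha A^H (A m_t - y)

with a learned regularization step ``m_{t+1} = D_phi(z_{t+1})``, where
``D_phi`` is a small fully complex CNN: complex convolutions
``W * d = (X*a - Y*b) + i(Y*a + X*b)`` for ``W = X + iY``, ``d = a + ib``,
CReLU activations ``ReLU(a) + i ReLU(b)``, and a global residual
connection (zero weights make the denoiser the identity).  Phase is first
class throughout: real and imaginary parts are never treated as separate
image channels.

Large volumes pass through the denoiser in overlapping blocks that are
stitched back by cutting each overlap at its midpoint, so every output
voxel comes from exactly one block and the identity function survives the
round trip bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import autodiff as ad
from .encoding import EncodingOperator


class ReconstructionDiverged(RuntimeError):
    """The unrolled iteration's norm exploded (step size too large)."""


@dataclass
class MoDLConfig:
    """Unroll / denoiser configuration.

    ``features=29`` makes the 5-layer complex ResNet's trainable parameter
    count (139 608) the closest realizable to the reference architecture's
    139 680 under the closed-form count
    ``sum_l 2 k^3 Cin_l Cout_l + 2 Cout_l`` — see :func:`parameter_count`.
    """

    n_unrolls: int = 6
    n_layers: int = 5
    features: int = 29
    kernel: int = 3
    alpha: float = 0.1
    block_size: int = 64
    block_overlap: int = 8
    share_weights: bool = True

    def __post_init__(self) -> None:
        if self.n_unrolls < 1:
            raise ValueError("need at least one unroll")
        if self.block_overlap >= self.block_size:
            raise ValueError("block overlap must be smaller than the block size")
        if not np.isfinite(self.alpha):
            raise ValueError("alpha must be finite")

    def layer_channels(self) -> list[tuple[int, int]]:
        f = self.features
        chans = [(1, f)]
        chans += [(f, f)] * (self.n_layers - 2)
        chans += [(f, 1)]
        return chans


@dataclass
class ComplexConvLayer:
    """Complex 3D convolution kernel W = X + iY with complex bias."""

    X: np.ndarray  # (Cout, Cin, k, k, k) real
    Y: np.ndarray
    bias_re: np.ndarray  # (Cout,)
    bias_im: np.ndarray

    def __post_init__(self) -> None:
        if self.X.shape != self.Y.shape:
            raise ValueError("X and Y kernels must share a shape")


def parameter_count(cfg: MoDLConfig) -> int:
    """Closed-form trainable parameter count of the denoiser."""
    k3 = cfg.kernel**3
    total = 0
    for cin, cout in cfg.layer_channels():
        total += 2 * k3 * cin * cout + 2 * cout
    return total


def init_denoiser(cfg: MoDLConfig, seed: int = 0, scale: float = 1.0) -> list[ComplexConvLayer]:
    """He-style initialization of the complex kernels (zero bias).

    The last layer starts at zero so the residual denoiser begins as the
    identity map — the unrolled iteration is then plain gradient descent
    at initialization and cannot amplify, whatever the seed."""
    rng = np.random.default_rng(seed)
    layers = []
    chans = cfg.layer_channels()
    for li, (cin, cout) in enumerate(chans):
        std = scale / np.sqrt(2.0 * cin * cfg.kernel**3)
        if li == len(chans) - 1:
            std = 0.0
        shape = (cout, cin, cfg.kernel, cfg.kernel, cfg.kernel)
        layers.append(
            ComplexConvLayer(
                X=std * rng.standard_normal(shape),
                Y=std * rng.standard_normal(shape),
                bias_re=np.zeros(cout),
                bias_im=np.zeros(cout),
            )
        )
    return layers


def zero_denoiser(cfg: MoDLConfig) -> list[ComplexConvLayer]:
    """All-zero weights: with the residual connection, the identity map."""
    layers = init_denoiser(cfg, seed=0)
    for l in layers:
        l.X[:] = 0
        l.Y[:] = 0
    return layers


# ---------------------------------------------------------------------------
# Complex convolution (im2col) and CReLU
# ---------------------------------------------------------------------------


def crelu(d: np.ndarray) -> np.ndarray:
    """CReLU: elementwise ReLU on real and imaginary parts independently."""
    return np.maximum(d.real, 0.0) + 1j * np.maximum(d.imag, 0.0)


def _patches(x: np.ndarray, k: int) -> np.ndarray:
    """Zero-padded sliding patches: (Cin, Nx, Ny, Nz, k, k, k)."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    return sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))


def _real_conv(patches: np.ndarray, kern: np.ndarray) -> np.ndarray:
    """Cross-correlation of real patches with a real kernel bank."""
    return np.einsum("cxyzijk,ocijk->oxyz", patches, kern, optimize=True)


def complex_conv(d: np.ndarray, layer: ComplexConvLayer) -> np.ndarray:
    """W * d = (X*a - Y*b) + i(Y*a + X*b): exactly four real convolutions.

    ``d`` has shape (Cin, Nx, Ny, Nz); output (Cout, Nx, Ny, Nz); "same"
    zero padding.
    """
    k = layer.X.shape[-1]
    pa = _patches(np.ascontiguousarray(d.real), k)
    pb = _patches(np.ascontiguousarray(d.imag), k)
    re = _real_conv(pa, layer.X) - _real_conv(pb, layer.Y)
    im = _real_conv(pa, layer.Y) + _real_conv(pb, layer.X)
    out = re + 1j * im
    bias = layer.bias_re + 1j * layer.bias_im
    return out + bias[:, None, None, None]


def _adjoint_layer(layer: ComplexConvLayer) -> ComplexConvLayer:
    """Kernel of the adjoint convolution: conj(W), flipped, channels swapped."""
    flip = (slice(None), slice(None), slice(None, None, -1)) * 1
    Xa = np.ascontiguousarray(layer.X.transpose(1, 0, 2, 3, 4)[..., ::-1, ::-1, ::-1])
    Ya = np.ascontiguousarray(-layer.Y.transpose(1, 0, 2, 3, 4)[..., ::-1, ::-1, ::-1])
    cout_in = layer.X.shape[1]
    return ComplexConvLayer(
        X=Xa, Y=Ya, bias_re=np.zeros(cout_in), bias_im=np.zeros(cout_in)
    )


def denoiser_forward(z: np.ndarray, cfg: MoDLConfig, weights) -> np.ndarray:
    """Plain (inference) denoiser: n_layers complex convs, CReLU between
    hidden layers, global residual connection.  ``z`` is (Nx, Ny, Nz)."""
    h = z[None]
    for li, layer in enumerate(weights):
        h = complex_conv(h, layer)
        if li < len(weights) - 1:
            h = crelu(h)
    return z + h[0]


def denoiser(z, cfg: MoDLConfig, weights):
    """Apply the denoiser blockwise when the volume exceeds the block size."""
    from .encoding import ImageVolume

    vol = z.data if isinstance(z, ImageVolume) else np.asarray(z)
    fn = lambda block: denoiser_forward(block, cfg, weights)
    return blockwise_apply(vol, fn, cfg.block_size, cfg.block_overlap)


# ---------------------------------------------------------------------------
# Blockwise processing
# ---------------------------------------------------------------------------


def _axis_partition(length: int, block: int, overlap: int):
    """(block_range, core_range) pairs along one axis.

    Blocks overlap by >= ``overlap``; each overlap is cut at its midpoint so
    the cores partition [0, length) exactly (single block if it fits)."""
    if block >= length:
        return [((0, length), (0, length))]
    stride = block - overlap
    starts = list(range(0, length - block, stride))
    starts.append(length - block)
    cuts = [0]
    for s0, s1 in zip(starts[:-1], starts[1:]):
        cuts.append((s1 + s0 + block) // 2)
    cuts.append(length)
    return [
        ((s, s + block), (cuts[i], cuts[i + 1])) for i, s in enumerate(starts)
    ]


def block_partition(shape, block: int, overlap: int):
    """All 3D blocks as (block_slices, core_out_slices, core_in_slices)."""
    per_axis = [_axis_partition(n, block, overlap) for n in shape]
    out = []
    for bx, cx in per_axis[0]:
        for by, cy in per_axis[1]:
            for bz, cz in per_axis[2]:
                blk = tuple(slice(b[0], b[1]) for b in (bx, by, bz))
                core = tuple(slice(c[0], c[1]) for c in (cx, cy, cz))
                core_in = tuple(
                    slice(c[0] - b[0], c[1] - b[0]) for b, c in zip((bx, by, bz), (cx, cy, cz))
                )
                out.append((blk, core, core_in))
    return out


def blockwise_apply(volume: np.ndarray, fn, block_size: int, overlap: int) -> np.ndarray:
    """Apply ``fn`` to overlapping blocks and stitch the cores back.

    The core regions partition the volume, so ``fn = identity`` returns the
    input bit for bit.
    """
    if overlap >= block_size:
        raise ValueError("overlap must be smaller than the block size")
    out = np.empty_like(np.asarray(volume))
    for blk, core, core_in in block_partition(volume.shape, block_size, overlap):
        out[core] = fn(volume[blk])[core_in]
    return out


# ---------------------------------------------------------------------------
# Data consistency and the unrolled loop (inference path)
# ---------------------------------------------------------------------------


def dc_step(m: np.ndarray, y: np.ndarray, op: EncodingOperator, alpha: float) -> np.ndarray:
    """One proximal-gradient step on ||A m - y||^2:  m - 2 alpha A^H(A m - y)."""
    return m - 2.0 * alpha * op.adjoint(op.forward(m) - y)


def unrolled_recon(
    y: np.ndarray,
    op: EncodingOperator,
    cfg: MoDLConfig,
    weights,
    alpha: float | None = None,
) -> np.ndarray:
    """MoDL inference: m_0 = A^H y, then alternate DC and denoiser steps."""
    alpha = cfg.alpha if alpha is None else alpha
    y = np.asarray(y).reshape(op.n_coils, -1)
    m = op.adjoint(y)
    norm0 = np.linalg.norm(m) + 1e-30
    for _ in range(cfg.n_unrolls):
        z = dc_step(m, y, op, alpha)
        m = denoiser(z, cfg, weights)
        if np.linalg.norm(m) > 1e6 * norm0 or not np.all(np.isfinite(m)):
            raise ReconstructionDiverged(
                "reconstruction norm exploded; reduce alpha or check scaling"
            )
    return m


def suggest_alpha(op: EncodingOperator, seed: int = 0) -> float:
    """Initial step size 0.5 / L with L = ||A^H A|| from power iteration."""
    return 0.5 / op.max_eigenvalue(seed=seed)


# ---------------------------------------------------------------------------
# Differentiable (training) path: ops over autodiff Vars
# ---------------------------------------------------------------------------


def crelu_op(d: ad.Var) -> ad.Var:
    mask_r = d.value.real > 0
    mask_i = d.value.imag > 0
    out = ad.Var(crelu(d.value), parents=(d,))

    def bwd(g):
        if d.requires_grad:
            d.accumulate(g.real * mask_r + 1j * (g.imag * mask_i))

    out._backward = bwd
    return out


def complex_conv_op(d: ad.Var, X: ad.Var, Y: ad.Var, br: ad.Var, bi: ad.Var) -> ad.Var:
    """Differentiable complex convolution over (Cin, Nx, Ny, Nz) input."""
    layer = ComplexConvLayer(X=X.value, Y=Y.value, bias_re=br.value, bias_im=bi.value)
    out = ad.Var(complex_conv(d.value, layer), parents=(d, X, Y, br, bi))
    k = X.value.shape[-1]

    def bwd(g):
        g = np.ascontiguousarray(g)
        if d.requires_grad:
            adj = _adjoint_layer(layer)
            ga = _patches(np.ascontiguousarray(g.real), k)
            gb = np.ascontiguousarray(g.imag)
            gb = _patches(gb, k)
            re = _real_conv(ga, adj.X) - _real_conv(gb, adj.Y)
            im = _real_conv(ga, adj.Y) + _real_conv(gb, adj.X)
            d.accumulate(re + 1j * im)
        if X.requires_grad or Y.requires_grad:
            # complex weight cotangent G_W = sum g_out . conj(patches)
            pa = _patches(np.ascontiguousarray(d.value.real), k)
            pb = _patches(np.ascontiguousarray(d.value.imag), k)
            # real parts: Re[G] = g_re.pa + g_im.pb ; Im[G] = g_im.pa - g_re.pb
            gre, gim = g.real, g.imag
            re_g = np.einsum("oxyz,cxyzijk->ocijk", gre, pa, optimize=True) + np.einsum(
                "oxyz,cxyzijk->ocijk", gim, pb, optimize=True
            )
            im_g = np.einsum("oxyz,cxyzijk->ocijk", gim, pa, optimize=True) - np.einsum(
                "oxyz,cxyzijk->ocijk", gre, pb, optimize=True
            )
            if X.requires_grad:
                X.accumulate(re_g)
            if Y.requires_grad:
                Y.accumulate(im_g)
        if br.requires_grad:
            br.accumulate(g.real.sum(axis=(1, 2, 3)))
        if bi.requires_grad:
            bi.accumulate(g.imag.sum(axis=(1, 2, 3)))

    out._backward = bwd
    return out


def _expand_channel_op(z: ad.Var) -> ad.Var:
    out = ad.Var(z.value[None], parents=(z,))

    def bwd(g):
        if z.requires_grad:
            z.accumulate(g[0])

    out._backward = bwd
    return out


def _squeeze_channel_op(h: ad.Var) -> ad.Var:
    out = ad.Var(h.value[0], parents=(h,))

    def bwd(g):
        if h.requires_grad:
            h.accumulate(g[None])

    out._backward = bwd
    return out


def _net_op(z: ad.Var, weight_vars) -> ad.Var:
    """The denoiser CNN (without the residual add) on a full volume/block."""
    h = _expand_channel_op(z)
    n = len(weight_vars)
    for li, (X, Y, br, bi) in enumerate(weight_vars):
        h = complex_conv_op(h, X, Y, br, bi)
        if li < n - 1:
            h = crelu_op(h)
    return _squeeze_channel_op(h)


def _slice_op(x: ad.Var, sl) -> ad.Var:
    out = ad.Var(x.value[sl], parents=(x,))

    def bwd(g):
        if x.requires_grad:
            gx = np.zeros(x.value.shape, dtype=g.dtype)
            gx[sl] = g
            x.accumulate(gx)

    out._backward = bwd
    return out


def _stitch_op(blocks, regions, shape) -> ad.Var:
    """Assemble block cores into a full volume (exact partition)."""
    value = np.empty(shape, dtype=blocks[0].value.dtype)
    for b, (_, core, core_in) in zip(blocks, regions):
        value[core] = b.value[core_in]
    out = ad.Var(value, parents=tuple(blocks))

    def bwd(g):
        for b, (_, core, core_in) in zip(blocks, regions):
            if b.requires_grad:
                gb = np.zeros(b.value.shape, dtype=g.dtype)
                gb[core_in] = g[core]
                b.accumulate(gb)

    out._backward = bwd
    return out


def denoiser_op(
    z: ad.Var,
    cfg: MoDLConfig,
    weight_vars,
    use_checkpoint: bool = True,
) -> ad.Var:
    """Differentiable denoiser with optional gradient checkpointing and
    blockwise evaluation; returns z + CNN(z)."""
    shape = z.value.shape
    regions = block_partition(shape, cfg.block_size, cfg.block_overlap)

    def run_block(zb, *wvars):
        grouped = [tuple(wvars[i : i + 4]) for i in range(0, len(wvars), 4)]
        return _net_op(zb, grouped)

    flat_w = [v for layer in weight_vars for v in layer]
    outs = []
    for blk, _, _ in regions:
        zb = _slice_op(z, blk) if len(regions) > 1 else z
        if use_checkpoint:
            outs.append(ad.checkpoint(run_block, zb, *flat_w))
        else:
            outs.append(run_block(zb, *flat_w))
    net = (
        _stitch_op(outs, regions, shape) if len(regions) > 1 else outs[0]
    )
    return ad.add(z, net)


def checkpointed_denoiser(z: ad.Var, cfg: MoDLConfig, weight_vars) -> ad.Var:
    """Denoiser whose backward recomputes activations from the stored input."""
    return denoiser_op(z, cfg, weight_vars, use_checkpoint=True)


def weights_to_vars(weights, requires_grad: bool = True):
    """Wrap ComplexConvLayer arrays as autodiff leaves (X, Y, b_re, b_im)."""
    out = []
    for li, l in enumerate(weights):
        out.append(
            (
                ad.leaf(l.X, requires_grad, name=f"X{li}"),
                ad.leaf(l.Y, requires_grad, name=f"Y{li}"),
                ad.leaf(l.bias_re, requires_grad, name=f"br{li}"),
                ad.leaf(l.bias_im, requires_grad, name=f"bi{li}"),
            )
        )
    return out


def vars_to_weights(weight_vars) -> list[ComplexConvLayer]:
    return [
        ComplexConvLayer(
            X=np.array(X.value), Y=np.array(Y.value),
            bias_re=np.array(br.value), bias_im=np.array(bi.value),
        )
        for X, Y, br, bi in weight_vars
    ]


def unrolled_recon_op(
    y: ad.Var,
    coords: ad.Var,
    make_op,
    cfg: MoDLConfig,
    weight_vars,
    alpha: ad.Var,
    use_checkpoint: bool = True,
    coord_backward: str = "jacobian",
) -> ad.Var:
    """Differentiable unrolled reconstruction (training path)."""
    m = ad.nufft_adjoint_op(y, coords, make_op)
    for _ in range(cfg.n_unrolls):
        am = ad.nufft_forward_op(m, coords, make_op, backward_mode=coord_backward)
        r = ad.sub(am, y)
        ahr = ad.nufft_adjoint_op(r, coords, make_op)
        z = ad.dc_combine(m, ahr, alpha)
        m = denoiser_op(z, cfg, weight_vars, use_checkpoint=use_checkpoint)
        if not np.all(np.isfinite(m.value)):
            raise ReconstructionDiverged("non-finite values during unrolling")
    return m
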