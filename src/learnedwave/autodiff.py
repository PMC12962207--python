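"""Minimal reverse-mode autodiff over complex numpy arrays.

Built for one job: backpropagating a real scalar loss through the unrolled
reconstruction, the encoding operator, and the wave parameterization, with
*custom* coordinate backward passes (analytic NUFFT Jacobians) instead of
differentiating the gridding kernel.

Gradient convention (matches PyTorch's complex autograd): for a complex
variable ``z`` the stored gradient is ``g = 2 * dL/d(conj z)``, i.e. the
direction of steepest ascent; for real-valued leaves (coordinates, wave
parameters, step size, the real/imaginary kernel banks) it is the ordinary
real derivative.  Linear complex ops propagate ``g`` through their
Hermitian transpose; a real parameter ``x`` entering a complex node ``z``
receives ``dL/dx = Re[ sum conj(g_z) * dz/dx ]``.
"""

from __future__ import annotations

import numpy as np

#: coordinate-backward implementations registered by
#: :func:`learnedwave.gradients.register_custom_backward`.
COORD_BACKWARD: dict = {}


def _ensure_registered() -> None:
    if "jacobian" not in COORD_BACKWARD:
        from . import gradients

        gradients.register_custom_backward()


class Var:
    """A node in the computation graph."""

    __slots__ = ("value", "grad", "parents", "_backward", "requires_grad", "name")

    def __init__(self, value, requires_grad=False, parents=(), backward=None, name=""):
        self.value = np.asarray(value)
        self.grad = None
        self.parents = tuple(parents)
        self._backward = backward
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p in parents
        )
        self.name = name

    def accumulate(self, g) -> None:
        if self.grad is None:
            self.grad = np.array(g, copy=True)
        else:
            self.grad = self.grad + g

    def zero_grad(self) -> None:
        self.grad = None

    def __repr__(self) -> str:  # pragma: no cover
        return f"Var({self.name or 'node'}, shape={self.value.shape})"


def leaf(value, requires_grad: bool = True, name: str = "") -> Var:
    return Var(value, requires_grad=requires_grad, name=name)


def constant(value, name: str = "") -> Var:
    return Var(value, requires_grad=False, name=name)


def _topo(root: Var) -> list[Var]:
    order: list[Var] = []
    seen: set[int] = set()
    stack: list[tuple[Var, bool]] = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node.parents:
            if p.requires_grad and id(p) not in seen:
                stack.append((p, False))
    return order


def backward(loss: Var, seed=1.0) -> None:
    """Reverse sweep from a (real scalar) loss node."""
    loss.accumulate(np.asarray(seed, dtype=float))
    for node in reversed(_topo(loss)):
        if node._backward is not None and node.grad is not None:
            node._backward(node.grad)


def graph_saved_bytes(root: Var) -> int:
    """Bytes of array values held alive by the graph (memory diagnostic)."""
    return sum(n.value.nbytes for n in _topo(root))


# ---------------------------------------------------------------------------
# Arithmetic primitives
# ---------------------------------------------------------------------------


def add(a: Var, b: Var) -> Var:
    out = Var(a.value + b.value, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(g)

    out._backward = bwd
    return out


def sub(a: Var, b: Var) -> Var:
    out = Var(a.value - b.value, parents=(a, b))

    def bwd(g):
        if a.requires_grad:
            a.accumulate(g)
        if b.requires_grad:
            b.accumulate(-g)

    out._backward = bwd
    return out


def dc_combine(m: Var, b: Var, alpha: Var) -> Var:
    """z = m - 2*alpha*b with ``alpha`` a real scalar leaf (the DC step)."""
    out = Var(m.value - 2.0 * float(alpha.value) * b.value, parents=(m, b, alpha))

    def bwd(g):
        if m.requires_grad:
            m.accumulate(g)
        if b.requires_grad:
            b.accumulate(-2.0 * float(alpha.value) * g)
        if alpha.requires_grad:
            alpha.accumulate(np.real(np.vdot(g, -2.0 * b.value)))

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Encoding-operator ops with custom coordinate backward
# ---------------------------------------------------------------------------


def nufft_forward_op(m: Var, coords: Var, make_op, backward_mode: str = "jacobian") -> Var:
    """y = A(coords) m.  ``make_op(coords_value)`` builds the EncodingOperator.

    The coordinate backward uses the analytic spectral Jacobian
    (``backward_mode='jacobian'``) or the interpolation-kernel derivative
    (``'kernel'``, for comparison experiments).
    """
    _ensure_registered()
    op = make_op(coords.value)
    out = Var(op.forward(m.value), parents=(m, coords))

    def bwd(g):
        if m.requires_grad:
            m.accumulate(op.adjoint(g))
        if coords.requires_grad:
            fwd_jvp, _ = COORD_BACKWARD[backward_mode]
            coords.accumulate(fwd_jvp(m.value, op, g / 2.0))

    out._backward = bwd
    return out


def nufft_adjoint_op(y: Var, coords: Var, make_op) -> Var:
    """m = A(coords)^H y with analytic coordinate backward."""
    _ensure_registered()
    op = make_op(coords.value)
    out = Var(op.adjoint(y.value), parents=(y, coords))

    def bwd(g):
        if y.requires_grad:
            y.accumulate(op.forward(g))
        if coords.requires_grad:
            _, adj_jvp = COORD_BACKWARD["jacobian"]
            coords.accumulate(adj_jvp(y.value, op, g / 2.0))

    out._backward = bwd
    return out


def wave_coords_op(kyc: Var, kzc: Var, sr: Var, theta: Var, wp, hs_template) -> Var:
    """Full flattened coordinates (P, 3) from the wave learnables."""
    from dataclasses import replace

    from .gradients import chain_to_wave_params
    from .trajectory import build_trajectory

    hs = replace(
        hs_template,
        kyc=kyc.value,
        kzc=kzc.value,
        sr=np.clip(sr.value, 1e-12, 1.0),
        theta=theta.value,
    )
    traj = build_trajectory(wp, hs, mode="wave")
    out = Var(traj.flat_coords(), parents=(kyc, kzc, sr, theta))

    def bwd(g):
        d_sr, d_theta, d_kyc, d_kzc = chain_to_wave_params(g, hs, wp)
        if sr.requires_grad:
            sr.accumulate(d_sr)
        if theta.requires_grad:
            theta.accumulate(d_theta)
        if kyc.requires_grad:
            kyc.accumulate(d_kyc)
        if kzc.requires_grad:
            kzc.accumulate(d_kzc)

    out._backward = bwd
    return out


def straight_coords_op(kyc: Var, kzc: Var, wp, hs_template) -> Var:
    """No-wave coordinates: straight readout lines through the centers."""
    from dataclasses import replace

    from .gradients import chain_to_centers
    from .trajectory import build_trajectory

    hs = replace(hs_template, kyc=kyc.value, kzc=kzc.value)
    traj = build_trajectory(wp, hs, mode="no_wave")
    out = Var(traj.flat_coords(), parents=(kyc, kzc))

    def bwd(g):
        d_kyc, d_kzc = chain_to_centers(g, hs.npe, wp.nro)
        if kyc.requires_grad:
            kyc.accumulate(d_kyc)
        if kzc.requires_grad:
            kzc.accumulate(d_kzc)

    out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# Loss and checkpointing
# ---------------------------------------------------------------------------


def nrmse(m_hat: Var, m_ref: Var) -> Var:
    """loss = sum|m_ref - m_hat|^2 / sum|m_ref|^2 (as-printed ratio form)."""
    ref = m_ref.value
    denom = float(np.sum(np.abs(ref) ** 2))
    if denom == 0:
        raise ValueError("all-zero reference image in NRMSE loss")
    diff = m_hat.value - ref
    out = Var(float(np.sum(np.abs(diff) ** 2) / denom), parents=(m_hat,))

    def bwd(g):
        if m_hat.requires_grad:
            m_hat.accumulate(float(g) * 2.0 * diff / denom)

    out._backward = bwd
    return out


def checkpoint(fn, *inputs: Var) -> Var:
    """Run ``fn`` without recording its interior; recompute on backward.

    ``fn`` must map Vars to a single Var deterministically.  Only the
    checkpoint's inputs (and output value) stay alive in the outer graph,
    trading recomputation time for memory exactly as gradient
    checkpointing does in DL frameworks.
    """
    detached = [Var(v.value, requires_grad=False) for v in inputs]
    with_value = fn(*detached)
    out = Var(with_value.value, parents=tuple(inputs))

    def bwd(g):
        inner = [Var(v.value, requires_grad=v.requires_grad) for v in inputs]
        inner_out = fn(*inner)
        for node in reversed(_topo(inner_out)):
            if node is inner_out:
                node.grad = np.array(g, copy=True)
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
        for v, iv in zip(inputs, inner):
            if v.requires_grad and iv.grad is not None:
                v.accumulate(iv.grad)

    out._backward = bwd
    return out
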