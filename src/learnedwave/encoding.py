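"""Multi-coil non-uniform Fourier forward model  y = C F S m + eps.

``EncodingOperator`` bundles coil sensitivity maps and a set of sampling
coordinates into the linear operator ``A`` mapping a complex image volume
to multi-channel k-space samples, together with its exact adjoint.  Two
engines are available: the Kaiser-Bessel gridded NUFFT (production) and a
direct-summation NDFT in float64 (exact, for oracles on small grids).

Density compensation is deliberately not applied inside the adjoint: the
unrolled reconstruction's data-consistency term works with the plain
normal equations ``A^H A``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nufft import KbNufft, NdftOperator
from .trajectory import Trajectory


@dataclass
class CoilSensitivities:
    """Coil maps, Ncoil x Nx x Ny x Nz complex, RSS-normalized in support."""

    maps: np.ndarray
    support_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.maps = np.asarray(self.maps)
        if self.maps.ndim != 4:
            raise ValueError("coil maps must have shape (Ncoil, Nx, Ny, Nz)")
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("coil maps must be finite")
        if self.support_mask is None:
            self.support_mask = np.ones(self.maps.shape[1:], dtype=bool)

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.maps.shape[1:]


@dataclass
class ImageVolume:
    """Complex image volume with voxel size in mm."""

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("image must be 3D")


@dataclass
class KSpaceData:
    """Sampled k-space, Ncoil x NPE x NRO complex (or Ncoil x P flattened)."""

    data: np.ndarray
    traj_ref: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)


def _as_coords(traj) -> np.ndarray:
    if isinstance(traj, Trajectory):
        return traj.flat_coords()
    coords = np.asarray(traj, dtype=float)
    if coords.ndim == 3:
        coords = coords.reshape(-1, 3)
    return coords


class EncodingOperator:
    """The multi-coil encoding operator A and its adjoint.

    Parameters
    ----------
    coils : CoilSensitivities or ndarray
    coords : Trajectory or ndarray (P, 3) / (NPE, NRO, 3), grid units
    engine : {"nufft", "ndft"}
        Gridded NUFFT (fast) or exact direct summation (small-scale oracle).
    oversamp, width :
        Kaiser-Bessel gridding parameters for the "nufft" engine.
    """

    def __init__(
        self,
        coils,
        coords,
        engine: str = "nufft",
        oversamp: float = 1.25,
        width: int = 4,
    ):
        if not isinstance(coils, CoilSensitivities):
            coils = CoilSensitivities(maps=np.asarray(coils))
        self.coils = coils
        self.coords = _as_coords(coords)
        if np.any(np.abs(self.coords) > max(coils.grid_shape) / 2):
            raise ValueError("coordinates outside [-N/2, N/2)")
        shape = coils.grid_shape
        if engine == "nufft":
            self.nufft = KbNufft(shape, oversamp=oversamp, width=width)
        elif engine == "ndft":
            self.nufft = NdftOperator(shape)
        else:
            raise ValueError(f"unknown engine {engine!r}")
        self.engine = engine
        self.grid_shape = shape

    @property
    def n_samples(self) -> int:
        return self.coords.shape[0]

    @property
    def n_coils(self) -> int:
        return self.coils.n_coils

    def forward(self, m: np.ndarray) -> np.ndarray:
        """A m: sample each coil-weighted image at the coordinates, (Nc, P)."""
        m = np.asarray(m)
        return self.nufft.forward_batch(self.coils.maps * m[None], self.coords)

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        """A^H y = sum_c conj(C_c) . F^H y_c."""
        y = np.asarray(y)
        out = np.zeros(self.grid_shape, dtype=np.complex128)
        for c in range(self.n_coils):
            out += np.conj(self.coils.maps[c]) * self.nufft.adjoint(y[c], self.coords)
        return out

    def normal(self, m: np.ndarray) -> np.ndarray:
        return self.adjoint(self.forward(m))

    def max_eigenvalue(self, seed: int = 0, n_iter: int = 20) -> float:
        """Largest eigenvalue of A^H A by power iteration."""
        rng = np.random.default_rng(seed)
        v = rng.standard_normal(self.grid_shape) + 1j * rng.standard_normal(
            self.grid_shape
        )
        lam = 1.0
        for _ in range(n_iter):
            w = self.normal(v)
            lam = float(np.linalg.norm(w) / np.linalg.norm(v))
            v = w / np.linalg.norm(w)
        return lam


def forward(m, coils, traj, **kw) -> KSpaceData:
    """Convenience wrapper: y = A m with a freshly built operator."""
    if isinstance(m, ImageVolume):
        m = m.data
    op = EncodingOperator(coils, traj, **kw)
    data = op.forward(m)
    if isinstance(traj, Trajectory):
        data = data.reshape(op.n_coils, traj.npe, traj.nro)
    return KSpaceData(data=data)


def adjoint(y, coils, traj, **kw) -> ImageVolume:
    if isinstance(y, KSpaceData):
        y = y.data
    y = np.asarray(y)
    op = EncodingOperator(coils, traj, **kw)
    return ImageVolume(data=op.adjoint(y.reshape(y.shape[0], -1)))


def add_noise(y, sigma: float, seed: int = 0):
    """Add i.i.d. Gaussian noise of std ``sigma`` to real and imaginary parts."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    data = y.data if isinstance(y, KSpaceData) else np.asarray(y)
    if sigma == 0:
        noisy = data.copy()
    else:
        rng = np.random.default_rng(seed)
        noisy = (
            data
            + sigma * rng.standard_normal(data.shape)
            + 1j * sigma * rng.standard_normal(data.shape)
        )
    if isinstance(y, KSpaceData):
        return KSpaceData(data=noisy, traj_ref=y.traj_ref)
    return noisy
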