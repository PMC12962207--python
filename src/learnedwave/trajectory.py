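"""Wave (helix) and straight-line readout trajectories with hardware limits.

Wave encoding plays sinusoidal gradients on the phase-encode axes (ky, kz)
during a constant-gradient readout along kx, so each readout traces a helix
("corkscrew") in k-space.  A single base helix, parameterized by its maximum
radius ``r``, cycle count ``C`` and echo fraction ``ef``, is shared by all
phase encodes; each phase encode ``j`` carries its own learnable center
``(kyc[j], kzc[j])``, radius down-scaling ``sr[j] in (0, 1]`` and rotation
``theta[j]`` about the kx axis:

    ky[j, i] = sr[j] * r * sin(t[i] + theta[j]) + kyc[j]
    kz[j, i] = sr[j] * r * cos(t[i] + theta[j]) + kzc[j]

where ``t[i]`` is the helix phase of readout sample ``i``.  Coordinates are
expressed in k-space grid units (cycles/FOV), so the sampled band is
``[-N/2, N/2)`` for matrix size ``N``.  Hardware compliance (gradient
amplitude and slew rate) is enforced by scaling each helix radius down,
never up, keeping the readout length fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Literal

import numpy as np

#: Gyromagnetic ratio of protons, Hz/T (gamma-bar).
GAMMA_BAR_HZ_PER_T = 42.577478518e6


class ConstraintError(ValueError):
    """A trajectory parameter violates its physical or box constraint."""


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------


@dataclass
class WaveParams:
    """Shared wave-readout parameterization.

    Attributes
    ----------
    r : float
        Maximum helix radius, k-space grid units (cycles/FOV).
    cycles : int
        Number of helix cycles ``C`` over a full echo.
    echo_fraction : float
        Acquired fraction of the readout k-space extent, in (0.5, 1].
    nro : int
        Readout samples per helix.
    gmax : float
        Maximum gradient amplitude, mT/m.
    smax : float
        Maximum slew rate, T/m/s.
    dwell : float
        Readout sample spacing, s.
    fov : float
        Field of view per axis, mm.
    matrix : int
        Grid size N per axis.
    """

    r: float
    cycles: int = 8
    echo_fraction: float = 0.75
    nro: int = 675
    gmax: float = 9.0
    smax: float = 150.0
    dwell: float = 4e-6
    fov: float = 220.0
    matrix: int = 256

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ConstraintError("helix radius r must be positive")
        if not 0.5 < self.echo_fraction <= 1.0:
            raise ConstraintError("echo fraction must lie in (0.5, 1]")
        if self.cycles < 1:
            raise ConstraintError("cycle count must be >= 1")
        if self.nro < 2:
            raise ConstraintError("readout needs at least 2 samples")
        if self.dwell <= 0 or self.fov <= 0 or self.matrix < 2:
            raise ConstraintError("dwell, fov and matrix must be positive")

    @property
    def echo_index(self) -> float:
        """Fractional readout index at which the echo (kx = 0) is crossed."""
        ef = self.echo_fraction
        return self.nro * (ef - 0.5) / ef

    @classmethod
    def from_hardware(
        cls,
        *,
        cycles: int = 8,
        echo_fraction: float = 0.75,
        nro: int = 675,
        gmax: float = 9.0,
        smax: float = 150.0,
        dwell: float = 4e-6,
        fov: float = 220.0,
        matrix: int = 256,
        radius_cap_fraction: float = 0.25,
    ) -> "WaveParams":
        """Build parameters with the largest radius the hardware allows.

        The base radius is never printed as a number by trajectory designs
        driven from gradient limits; it is derived here from ``gmax`` and
        ``smax`` under the grid-unit gradient mapping, then capped at
        ``radius_cap_fraction * matrix`` grid units to stay inside k-space.
        """
        probe = cls(
            r=1.0, cycles=cycles, echo_fraction=echo_fraction, nro=nro,
            gmax=gmax, smax=smax, dwell=dwell, fov=fov, matrix=matrix,
        )
        r = max_radius_from_hardware(probe)
        r = min(r, radius_cap_fraction * matrix)
        return replace(probe, r=r)


@dataclass
class HelixSet:
    """Per-phase-encode learnable trajectory parameters."""

    kyc: np.ndarray
    kzc: np.ndarray
    sr: np.ndarray
    theta: np.ndarray
    learnable_mask: tuple[str, ...] = ("kyc", "kzc", "sr", "theta")

    def __post_init__(self) -> None:
        self.kyc = np.asarray(self.kyc, dtype=float)
        self.kzc = np.asarray(self.kzc, dtype=float)
        self.sr = np.asarray(self.sr, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        npe = self.kyc.shape[0]
        for name in ("kzc", "sr", "theta"):
            if getattr(self, name).shape != (npe,):
                raise ConstraintError(f"{name} must have length {npe}")
        if np.any(self.sr <= 0) or np.any(self.sr > 1):
            raise ConstraintError("helix radius scaling sr must lie in (0, 1]")

    @property
    def npe(self) -> int:
        return self.kyc.shape[0]

    @classmethod
    def from_centers(cls, kyc, kzc, mode: str = "wave") -> "HelixSet":
        kyc = np.asarray(kyc, dtype=float)
        npe = kyc.shape[0]
        learnable = ("kyc", "kzc", "sr", "theta") if mode == "wave" else ("kyc", "kzc")
        return cls(
            kyc=kyc,
            kzc=np.asarray(kzc, dtype=float),
            sr=np.ones(npe),
            theta=np.zeros(npe),
            learnable_mask=learnable,
        )


@dataclass
class Trajectory:
    """Full sampling coordinates, NPE x NRO x 3 (kx, ky, kz), grid units."""

    coords: np.ndarray
    mode: Literal["wave", "no_wave"]
    wave_params: WaveParams
    helix_set: HelixSet | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ConstraintError("coords must have shape (NPE, NRO, 3)")

    @property
    def npe(self) -> int:
        return self.coords.shape[0]

    @property
    def nro(self) -> int:
        return self.coords.shape[1]

    def flat_coords(self) -> np.ndarray:
        """Coordinates flattened to (NPE*NRO, 3) for the encoding operator."""
        return self.coords.reshape(-1, 3)


# ---------------------------------------------------------------------------
# Helix construction
# ---------------------------------------------------------------------------


def helix_phase(i, wp: WaveParams):
    """Helix phase (radians) of readout sample ``i``.

        t[i] = -2*pi*C * [(ef - 1/2) - (ef/NRO) * i]

    Monotonically increasing in ``i`` and zero at the echo index
    ``NRO*(ef - 1/2)/ef``, so the echo center kx = 0 is always crossed.
    """
    i = np.asarray(i, dtype=float)
    if np.any(i < 0) or np.any(i > wp.nro):
        raise IndexError(f"readout index out of range [0, {wp.nro}]")
    ef = wp.echo_fraction
    return -2.0 * np.pi * wp.cycles * ((ef - 0.5) - ef * i / wp.nro)


def kx_from_phase(phase, wp: WaveParams):
    """Map helix phase linearly to the kx grid coordinate.

    The mapping ``kx = phase * N / (2*pi*C)`` places the echo (phase 0) at
    kx = 0 and spans ``[-(ef - 1/2)*N, +N/2]`` over the full readout — the
    partial-echo band of an echo-fraction-``ef`` acquisition.
    """
    return np.asarray(phase) * wp.matrix / (2.0 * np.pi * wp.cycles)


def build_helix(
    wp: WaveParams,
    sr: float,
    theta: float,
    center: tuple[float, float],
) -> np.ndarray:
    """Coordinates (NRO x 3) of one wave readout.

    The sin/cos argument is the helix phase itself, so every sample sits at
    transverse distance ``sr * r`` from ``center``.
    """
    if not 0.0 < sr <= 1.0:
        raise ConstraintError("sr must lie in (0, 1]")
    i = np.arange(wp.nro)
    t = helix_phase(i, wp)
    kyc, kzc = center
    out = np.empty((wp.nro, 3))
    out[:, 0] = kx_from_phase(t, wp)
    out[:, 1] = sr * wp.r * np.sin(t + theta) + kyc
    out[:, 2] = sr * wp.r * np.cos(t + theta) + kzc
    return out


def build_straight_readout(wp: WaveParams, center: tuple[float, float]) -> np.ndarray:
    """Straight-line ("no-wave") readout through (kyc, kzc): the sr -> 0 limit."""
    i = np.arange(wp.nro)
    out = np.empty((wp.nro, 3))
    out[:, 0] = kx_from_phase(helix_phase(i, wp), wp)
    out[:, 1] = center[0]
    out[:, 2] = center[1]
    return out


def build_trajectory(
    wp: WaveParams,
    hs: HelixSet,
    mode: Literal["wave", "no_wave"] = "wave",
) -> Trajectory:
    """Assemble the full NPE x NRO x 3 trajectory from the shared base helix."""
    i = np.arange(wp.nro)
    t = helix_phase(i, wp)
    kx = kx_from_phase(t, wp)
    coords = np.empty((hs.npe, wp.nro, 3))
    coords[:, :, 0] = kx[None, :]
    if mode == "wave":
        arg = t[None, :] + hs.theta[:, None]
        amp = (hs.sr * wp.r)[:, None]
        coords[:, :, 1] = amp * np.sin(arg) + hs.kyc[:, None]
        coords[:, :, 2] = amp * np.cos(arg) + hs.kzc[:, None]
    elif mode == "no_wave":
        coords[:, :, 1] = hs.kyc[:, None]
        coords[:, :, 2] = hs.kzc[:, None]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    meta = {
        "mode": mode,
        "kx_mapping": "kx = phase * N / (2*pi*C); echo at kx=0; "
        "span [-(ef-1/2)*N, +N/2]",
        "r": wp.r,
        "cycles": wp.cycles,
        "echo_fraction": wp.echo_fraction,
    }
    return Trajectory(coords=coords, mode=mode, wave_params=wp, helix_set=hs, meta=meta)


# ---------------------------------------------------------------------------
# Gradient waveforms and hardware constraints
# ---------------------------------------------------------------------------


def traj_to_gradient(t: Trajectory | np.ndarray, wp: WaveParams):
    """Gradient and slew waveforms implied by a trajectory.

    k-space grid units are cycles/FOV, so the physical wavenumber is
    ``k / FOV`` (cycles/m) and

        g[i]    = (k[i+1] - k[i]) / (gamma_bar * dwell * FOV)   [T/m]
        slew[i] = (g[i+1] - g[i]) / dwell                       [T/m/s]

    Returns
    -------
    g : ndarray, shape (NPE, NRO-1, 3), mT/m
    slew : ndarray, shape (NPE, NRO-2, 3), T/m/s
    """
    coords = t.coords if isinstance(t, Trajectory) else np.asarray(t, dtype=float)
    if coords.ndim == 2:
        coords = coords[None]
    fov_m = wp.fov * 1e-3
    dk = np.diff(coords, axis=1) / fov_m  # cycles/m per dwell
    g_t_per_m = dk / (GAMMA_BAR_HZ_PER_T * wp.dwell)
    slew = np.diff(g_t_per_m, axis=1) / wp.dwell
    return g_t_per_m * 1e3, slew


def _transverse_scale_limit(g_mt, slew, gmax: float, smax: float) -> float:
    """Largest factor s so that scaling the transverse (y, z) gradient
    components by s keeps |g| <= gmax and |slew| <= smax."""
    gx2 = g_mt[..., 0] ** 2
    gt2 = g_mt[..., 1] ** 2 + g_mt[..., 2] ** 2
    if np.any(gx2 > gmax**2 * (1 + 1e-12)):
        raise ConstraintError(
            "readout (kx) gradient alone exceeds gmax; "
            "reduce matrix size or increase dwell/NRO"
        )
    head = gmax**2 - gx2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(gt2 > 0, head / np.maximum(gt2, 1e-300), np.inf)
    s_amp = float(np.sqrt(max(np.min(s2), 0.0)))

    sx2 = slew[..., 0] ** 2
    st2 = slew[..., 1] ** 2 + slew[..., 2] ** 2
    if np.any(sx2 > smax**2 * (1 + 1e-12)):
        raise ConstraintError("readout (kx) slew alone exceeds smax")
    head = smax**2 - sx2
    with np.errstate(divide="ignore", invalid="ignore"):
        s2 = np.where(st2 > 0, head / np.maximum(st2, 1e-300), np.inf)
    s_slew = float(np.sqrt(max(np.min(s2), 0.0)))
    return min(s_amp, s_slew)


def enforce_hardware(t: Trajectory, wp: WaveParams | None = None) -> Trajectory:
    """Scale each helix radius down until the waveform is hardware compliant.

    The radius can only shrink (scale factor <= 1); the readout length is
    unchanged.  Returns a new trajectory; per-helix scale factors are stored
    in ``meta['hardware_scale']``.
    """
    wp = wp or t.wave_params
    g, slew = traj_to_gradient(t, wp)
    npe = t.npe
    scales = np.ones(npe)
    hs = t.helix_set
    if t.mode == "no_wave":
        # transverse gradients are identically zero; only check kx.
        _transverse_scale_limit(g, slew, wp.gmax, wp.smax)
        t.meta["hardware_scale"] = scales
        return t
    centers = (
        np.stack([hs.kyc, hs.kzc], axis=1)
        if hs is not None
        else t.coords[:, :, 1:].mean(axis=1)
    )
    coords = t.coords.copy()
    for j in range(npe):
        s = _transverse_scale_limit(g[j], slew[j], wp.gmax, wp.smax)
        s = min(1.0, s)
        scales[j] = s
        if s < 1.0:
            coords[j, :, 1:] = centers[j] + s * (t.coords[j, :, 1:] - centers[j])
    new_hs = hs
    if hs is not None and np.any(scales < 1.0):
        new_hs = replace(hs, sr=np.clip(hs.sr * scales, 1e-12, 1.0))
    out = Trajectory(
        coords=coords, mode=t.mode, wave_params=wp, helix_set=new_hs,
        meta=dict(t.meta),
    )
    out.meta["hardware_scale"] = scales
    return out


def max_radius_from_hardware(wp: WaveParams) -> float:
    """Largest base helix radius (grid units) meeting gmax and smax.

    The transverse gradient of a radius-``r`` helix is sinusoidal with
    angular rate ``dphase/dt = 2*pi*C*ef/(NRO*dwell)``; both the gradient
    amplitude and the slew rate scale linearly in ``r``, so the bound is a
    simple minimum of the two closed-form limits (the kx contribution to
    |g| is accounted for by the hardware-enforcement scan afterwards).
    """
    fov_m = wp.fov * 1e-3
    rate = 2.0 * np.pi * wp.cycles * wp.echo_fraction / (wp.nro * wp.dwell)
    # ky = r sin(phase): peak d(ky)/dt = r * rate in grid units (cycles/FOV)
    # per second, so peak gradient is r * rate / (gamma_bar * FOV).  The
    # continuous bound dominates the discrete waveform (2 sin(d/2) <= d),
    # so a radius at this limit stays compliant after sampling.
    g_per_r = rate / (GAMMA_BAR_HZ_PER_T * fov_m)  # T/m per grid unit
    slew_per_r = g_per_r * rate
    r_g = (wp.gmax * 1e-3) / g_per_r
    r_s = wp.smax / slew_per_r
    return min(r_g, r_s)


# ---------------------------------------------------------------------------
# Poisson-disc initialization of phase-encode centers
# ---------------------------------------------------------------------------


def default_density(n: int) -> Callable[[np.ndarray], np.ndarray]:
    """Variable-density profile: fully sampled disc of radius N/32 at the
    k-space center, then linearly decreasing density out to the edge."""
    r_full = n / 32.0
    r_max = n / 2.0

    def density(rho: np.ndarray) -> np.ndarray:
        rho = np.asarray(rho, dtype=float)
        frac = np.clip((rho - r_full) / (r_max - r_full), 0.0, 1.0)
        return 1.0 - 0.95 * frac

    return density


def _dart_throw(
    n_grid: int,
    spacing: float,
    density: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
    max_failures: int = 2000,
) -> np.ndarray:
    """Sequential dart throwing with a cell grid for neighbor queries.

    Minimum pairwise distance at radius rho is ``spacing / sqrt(density(rho))``
    (evaluated at the candidate point), giving the requested density profile.
    """
    half = n_grid / 2.0
    r_base = spacing / np.sqrt(density(np.array(n_grid / 2.0)))
    cell = max(float(r_base), 1e-6)
    n_cells = int(np.ceil(n_grid / cell))
    grid: dict[tuple[int, int], list[int]] = {}
    pts: list[np.ndarray] = []
    failures = 0
    while failures < max_failures:
        p = rng.uniform(-half, half, size=2)
        rho = np.hypot(p[0], p[1])
        r_min = spacing / np.sqrt(max(float(density(np.array(rho))), 1e-6))
        ci = int((p[0] + half) / cell)
        cj = int((p[1] + half) / cell)
        reach = int(np.ceil(r_min / cell))
        ok = True
        for di in range(-reach, reach + 1):
            for dj in range(-reach, reach + 1):
                for idx in grid.get((ci + di, cj + dj), ()):
                    if np.hypot(*(pts[idx] - p)) < r_min:
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            grid.setdefault((ci, cj), []).append(len(pts))
            pts.append(p)
            failures = 0
        else:
            failures += 1
    return np.array(pts) if pts else np.empty((0, 2))


def poisson_disc_init(
    n_pe: int,
    n_grid: int,
    density: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
    max_search: int = 24,
) -> tuple[np.ndarray, np.ndarray]:
    """Variable-density Poisson-disc draw of exactly ``n_pe`` centers.

    Points lie in ``[-N/2, N/2)^2`` with local minimum spacing set by the
    density profile.  The base spacing is bisected until the maximal dart
    throw yields at least ``n_pe`` points, which are then thinned uniformly
    at random (seeded) to the exact count.  Identical seeds give identical
    points, so wave and no-wave runs can share one draw.
    """
    if n_pe < 1:
        raise ValueError("n_pe must be >= 1")
    density = density or default_density(n_grid)
    rng_master = np.random.default_rng(seed)
    trial_seeds = rng_master.integers(0, 2**31 - 1, size=max_search + 1)
    # initial spacing guess from area / target count
    spacing = 0.8 * n_grid / np.sqrt(n_pe)
    lo, hi = None, None
    pts = None
    for k in range(max_search):
        rng = np.random.default_rng(int(trial_seeds[k]))
        cand = _dart_throw(n_grid, spacing, density, rng)
        if len(cand) >= n_pe:
            pts = cand
            lo = spacing
            if hi is not None:
                spacing = 0.5 * (lo + hi)
            else:
                break
        else:
            hi = spacing
            spacing = 0.5 * lo + 0.5 * hi if lo is not None else spacing * 0.7
        if lo is not None and hi is not None and hi - lo < 1e-3 * hi:
            break
    if pts is None:
        raise ConstraintError(
            f"could not place {n_pe} Poisson-disc points in a {n_grid}^2 box "
            f"after {max_search} attempts"
        )
    keep = np.random.default_rng(int(trial_seeds[-1])).choice(
        len(pts), size=n_pe, replace=False
    )
    keep.sort()
    pts = pts[keep]
    return pts[:, 0].copy(), pts[:, 1].copy()
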