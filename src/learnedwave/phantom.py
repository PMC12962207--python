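"""Synthetic 4-point flow-encoded phantoms with known velocity fields.

Emulates a quantitative flow phantom — straight tubes with laminar
(parabolic) or plug flow inside a signal-giving background block — and
brain-like cases with several randomly curved vessels, on a Cartesian
grid with smooth synthetic coil maps.  Velocity maps directly to signal
phase with the standard PC-MRI convention: a speed of Venc along an
encoding axis produces a phase of pi relative to the reference encode.

Geometry is rasterized on a supersampled grid and box-averaged down, so
partial-volume voxels carry the volume-averaged magnitude and velocity;
the flow rate through any cross-section is then conserved to quadrature
accuracy, which the evaluation module exploits as a mass-conservation
oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial import cKDTree

from .encoding import CoilSensitivities


@dataclass
class Tube:
    """A straight tube along a principal axis, or a curved vessel.

    ``flow_lpm`` (L/min) sets the parabolic peak via
    v_peak = 2 Q / (pi R^2); alternatively give ``peak_cms`` directly.
    """

    center: tuple[float, float]  # in-plane position, mm (axis-perp plane)
    diameter_mm: float
    axis: str = "z"
    flow_lpm: float | None = None
    peak_cms: float | None = None
    profile: str = "parabolic"  # parabolic | plug
    control_points: np.ndarray | None = None  # (K, 3) mm, for curved vessels

    def radius_mm(self) -> float:
        return self.diameter_mm / 2.0

    def peak_speed_cms(self) -> float:
        if self.peak_cms is not None:
            return float(self.peak_cms)
        if self.flow_lpm is None:
            return 0.0
        r_cm = self.radius_mm() / 10.0
        q_cm3s = self.flow_lpm * 1000.0 / 60.0
        mean = q_cm3s / (np.pi * r_cm**2)
        return 2.0 * mean if self.profile == "parabolic" else mean


@dataclass
class PhantomSpec:
    """Full phantom description."""

    n_grid: int = 64
    voxel_mm: float = 1.0
    tubes: list[Tube] = field(default_factory=list)
    background: float = 0.2
    venc: float = 80.0
    n_coils: int = 8
    noise_sigma: float = 0.0
    seed: int = 0
    supersample: int = 2

    def __post_init__(self) -> None:
        for t in self.tubes:
            if t.profile == "parabolic" and t.diameter_mm <= 2 * self.voxel_mm:
                raise ValueError(
                    "parabolic tubes need diameter > 2 voxels "
                    f"(got {t.diameter_mm} mm at {self.voxel_mm} mm voxels)"
                )

    def fov_mm(self) -> float:
        return self.n_grid * self.voxel_mm


def flow_phantom_spec(
    n_grid: int = 64, voxel_mm: float = 1.0, **kw
) -> PhantomSpec:
    """The three-tube quantitative flow phantom: two small tubes
    (diameter 3 mm, 0.17 and 0.15 L/min) and a large tube
    (12.7 mm, 1.83 L/min).

    A tube too thin for a resolvable parabolic profile at the requested
    voxel size falls back to plug flow; the set flow rate is preserved
    either way (plug speed = mean speed)."""
    fov = n_grid * voxel_mm
    off = fov / 4.0

    def profile(diameter):
        return "parabolic" if diameter > 2.2 * voxel_mm else "plug"

    tubes = [
        Tube(center=(-off, -off), diameter_mm=3.0, flow_lpm=0.17, profile=profile(3.0)),
        Tube(center=(-off, off), diameter_mm=3.0, flow_lpm=0.15, profile=profile(3.0)),
        Tube(center=(off / 2.0, 0.0), diameter_mm=12.7, flow_lpm=1.83,
             profile=profile(12.7)),
    ]
    return PhantomSpec(n_grid=n_grid, voxel_mm=voxel_mm, tubes=tubes, **kw)


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------

_AXIS = {"x": 0, "y": 1, "z": 2}


def _supersampled_axes(spec: PhantomSpec):
    n = spec.n_grid * spec.supersample
    # voxel centers in mm, centered on the grid
    step = spec.voxel_mm / spec.supersample
    return (np.arange(n) - n / 2.0 + 0.5) * step


def _straight_tube_fields(spec: PhantomSpec, tube: Tube, coords):
    ax = _AXIS[tube.axis]
    perp = [d for d in range(3) if d != ax]
    u = coords[perp[0]] - tube.center[0]
    v = coords[perp[1]] - tube.center[1]
    rho2 = u**2 + v**2
    r = tube.radius_mm()
    inside = rho2 <= r**2
    vpk = tube.peak_speed_cms()
    if tube.profile == "parabolic":
        speed = vpk * np.clip(1.0 - rho2 / r**2, 0.0, None) * inside
    else:
        speed = vpk * inside
    vel = np.zeros((3,) + inside.shape)
    vel[ax] = speed
    return inside, vel


def _curved_tube_fields(spec: PhantomSpec, tube: Tube, coords):
    """Distance-to-centerline rasterization via a KD-tree of curve samples."""
    cp = np.asarray(tube.control_points, dtype=float)
    ts = np.linspace(0.0, 1.0, 40 * len(cp))
    # Catmull-Rom-ish: cubic Bezier through successive control quads is
    # overkill here; a fine polyline through the control points suffices.
    seg = np.linspace(0, len(cp) - 1, len(ts))
    lo = np.clip(seg.astype(int), 0, len(cp) - 2)
    w = (seg - lo)[:, None]
    pts = cp[lo] * (1 - w) + cp[lo + 1] * w
    tangents = np.gradient(pts, axis=0)
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True) + 1e-30
    tree = cKDTree(pts)
    flat = np.stack([c.reshape(-1) for c in coords], axis=1)
    dist, idx = tree.query(flat, workers=-1)
    r = tube.radius_mm()
    inside = (dist <= r).reshape(coords[0].shape)
    vpk = tube.peak_speed_cms()
    if tube.profile == "parabolic":
        speed = vpk * np.clip(1.0 - (dist / r) ** 2, 0.0, None)
    else:
        speed = vpk * (dist <= r)
    vel_flat = speed[:, None] * tangents[idx]
    vel = np.moveaxis(
        vel_flat.reshape(coords[0].shape + (3,)), -1, 0
    ) * inside[None]
    return inside, vel


def _downsample(arr: np.ndarray, factor: int) -> np.ndarray:
    """Box-average the trailing three axes by ``factor``."""
    shape = arr.shape
    n = shape[-1] // factor
    lead = shape[:-3]
    r = arr.reshape(lead + (n, factor, n, factor, n, factor))
    return r.mean(axis=(-5, -3, -1))


def build_geometry(spec: PhantomSpec):
    """Rasterize magnitude, velocity (cm/s) and vessel mask.

    Returns
    -------
    magnitude : (N, N, N) float — background plus tube lumen signal.
    velocity : (3, N, N, N) float, cm/s, volume-averaged; zero outside tubes.
    vessel_mask : (N, N, N) bool — voxels with any tube occupancy.
    """
    axes = _supersampled_axes(spec)
    coords = np.meshgrid(axes, axes, axes, indexing="ij")
    occ = np.zeros(coords[0].shape)
    vel = np.zeros((3,) + coords[0].shape)
    total = np.zeros(coords[0].shape, dtype=int)
    for tube in spec.tubes:
        if tube.control_points is not None:
            inside, v = _curved_tube_fields(spec, tube, coords)
        else:
            inside, v = _straight_tube_fields(spec, tube, coords)
        total += inside
        occ = np.maximum(occ, inside.astype(float))
        vel += v
    if np.any(total > 1):
        raise ValueError("tubes overlap")
    # signal: background block everywhere, brighter fluid in the lumen
    magnitude_ss = spec.background + (1.0 - spec.background) * occ
    magnitude = _downsample(magnitude_ss, spec.supersample)
    velocity = _downsample(vel, spec.supersample)
    vessel_mask = _downsample(occ, spec.supersample) > 0
    return magnitude, velocity, vessel_mask


# ---------------------------------------------------------------------------
# Flow encoding and coils
# ---------------------------------------------------------------------------


def flow_encode(
    magnitude: np.ndarray,
    velocity: np.ndarray,
    venc: float,
    background_phase: np.ndarray | float = 0.0,
) -> np.ndarray:
    """4-point referenced encoding: reference plus x/y/z encodes.

    encode 0:  magnitude * exp(i phi_bg)
    encode d:  magnitude * exp(i (phi_bg + pi * v_d / venc))
    """
    out = np.empty((4,) + magnitude.shape, dtype=np.complex128)
    ref_phase = np.broadcast_to(background_phase, magnitude.shape)
    out[0] = magnitude * np.exp(1j * ref_phase)
    for d in range(3):
        out[d + 1] = magnitude * np.exp(
            1j * (ref_phase + np.pi * velocity[d] / venc)
        )
    return out


def synth_coils(n_grid: int, n_coils: int, seed: int = 0) -> CoilSensitivities:
    """Smooth complex coil maps, RSS-normalized to 1 everywhere.

    Each coil is a low-order complex spatial polynomial plus a broad
    Gaussian sensitivity lobe centered outside the FOV, with a distinct
    phase offset — a stand-in with the smoothness of real receive maps.
    """
    if n_coils < 1:
        raise ValueError("need at least one coil")
    if n_coils == 1:
        maps = np.ones((1, n_grid, n_grid, n_grid), dtype=np.complex128)
        return CoilSensitivities(maps=maps)
    rng = np.random.default_rng(seed)
    ax = np.linspace(-0.5, 0.5, n_grid)
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    maps = np.empty((n_coils, n_grid, n_grid, n_grid), dtype=np.complex128)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils
        cx, cy = 0.9 * np.cos(ang), 0.9 * np.sin(ang)
        cz = rng.uniform(-0.3, 0.3)
        d2 = (X - cx) ** 2 + (Y - cy) ** 2 + (Z - cz) ** 2
        lobe = np.exp(-d2 / (2 * 0.45**2))
        poly = (
            1.0
            + rng.uniform(-0.3, 0.3) * X
            + rng.uniform(-0.3, 0.3) * Y
            + rng.uniform(-0.3, 0.3) * Z
        )
        phase = (
            rng.uniform(0, 2 * np.pi)
            + rng.uniform(-1.5, 1.5) * X
            + rng.uniform(-1.5, 1.5) * Y
            + rng.uniform(-1.5, 1.5) * Z
        )
        maps[c] = lobe * poly * np.exp(1j * phase)
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0, keepdims=True))
    maps /= rss
    return CoilSensitivities(maps=maps)


# ---------------------------------------------------------------------------
# Case assembly
# ---------------------------------------------------------------------------


@dataclass
class PhantomCase:
    """One fully specified case: truth, encodes, coils."""

    spec: PhantomSpec
    magnitude: np.ndarray
    velocity: np.ndarray
    vessel_mask: np.ndarray
    encoded: np.ndarray  # (4, N, N, N) complex
    coils: CoilSensitivities

    @property
    def volume(self) -> np.ndarray:
        """Reference-encode complex volume (training target)."""
        return self.encoded[0]


def build_case(spec: PhantomSpec) -> PhantomCase:
    magnitude, velocity, mask = build_geometry(spec)
    encoded = flow_encode(magnitude, velocity, spec.venc)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 7919)
        encoded = encoded + spec.noise_sigma * (
            rng.standard_normal(encoded.shape)
            + 1j * rng.standard_normal(encoded.shape)
        )
    coils = synth_coils(spec.n_grid, spec.n_coils, seed=spec.seed)
    return PhantomCase(
        spec=spec, magnitude=magnitude, velocity=velocity,
        vessel_mask=mask, encoded=encoded, coils=coils,
    )


def random_vessel_spec(
    n_grid: int,
    voxel_mm: float,
    seed: int,
    n_vessels: tuple[int, int] = (3, 6),
    diameter_range_mm: tuple[float, float] = (2.5, 13.0),
    peak_speed_range_cms: tuple[float, float] = (10.0, 60.0),
    n_coils: int = 4,
    noise_sigma: float = 0.0,
) -> PhantomSpec:
    """Brain-like case: several smooth curved vessels of mixed caliber."""
    rng = np.random.default_rng(seed)
    fov = n_grid * voxel_mm
    tubes = []
    n_v = int(rng.integers(n_vessels[0], n_vessels[1] + 1))
    for _ in range(n_v):
        k = int(rng.integers(3, 6))
        cp = rng.uniform(-0.42 * fov, 0.42 * fov, size=(k, 3))
        # spread control points along a random dominant direction
        order = np.argsort(cp @ rng.standard_normal(3))
        cp = cp[order]
        dia = float(
            np.clip(rng.uniform(*diameter_range_mm), 2.2 * voxel_mm, 0.3 * fov)
        )
        tubes.append(
            Tube(
                center=(0.0, 0.0),
                diameter_mm=dia,
                peak_cms=float(rng.uniform(*peak_speed_range_cms)),
                control_points=cp,
            )
        )
    return PhantomSpec(
        n_grid=n_grid, voxel_mm=voxel_mm, tubes=tubes,
        n_coils=n_coils, noise_sigma=noise_sigma, seed=seed,
    )


def build_vessel_case(n_grid: int, voxel_mm: float, seed: int, **kw) -> PhantomCase:
    """Brain-like case; vessel overlaps are re-drawn with fresh seeds."""
    for attempt in range(8):
        spec = random_vessel_spec(n_grid, voxel_mm, seed + 1000 * attempt, **kw)
        try:
            return build_case(spec)
        except ValueError:
            continue
    # fall back to a single straight tube (cannot overlap); still seeded
    rng = np.random.default_rng(seed)
    fov = n_grid * voxel_mm
    spec = PhantomSpec(
        n_grid=n_grid, voxel_mm=voxel_mm,
        tubes=[Tube(
            center=tuple(rng.uniform(-0.2 * fov, 0.2 * fov, 2)),
            diameter_mm=float(rng.uniform(0.15, 0.3)) * fov,
            peak_cms=float(rng.uniform(20.0, 60.0)),
            axis=str(rng.choice(["x", "y", "z"])),
        )],
        n_coils=kw.get("n_coils", 4), seed=seed,
    )
    return build_case(spec)


def make_dataset(specs: list[PhantomSpec], seed: int, out_dir=None):
    """Build cases (optionally writing HDF5 files) with a 9:1 train/val split.

    Returns (cases, manifest); the manifest lists file names and the split.
    """
    if len(specs) < 2:
        raise ValueError("need at least 2 specs to split")
    cases = [build_case(s) for s in specs]
    n_val = max(1, round(len(specs) / 10))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(specs))
    val_idx = sorted(int(i) for i in order[:n_val])
    manifest = {
        "n_cases": len(specs),
        "validation_indices": val_idx,
        "training_indices": [i for i in range(len(specs)) if i not in val_idx],
        "files": [],
    }
    if out_dir is not None:
        from . import io as lwio

        for i, case in enumerate(cases):
            path = f"{out_dir}/case_{i:03d}.h5"
            lwio.save_phantom_case(path, case)
            manifest["files"].append(path)
    return cases, manifest
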