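"""Desk-scale experiment recipes used by tests and the acceptance script.

These fix the scaled-down study conditions once: 32^3 grids (64 mm FOV,
2 mm voxels), 68 phase encodes (matching the full protocol's acceleration
factor at this matrix size), 84 readout samples spanning the full
protocol's 2.7 ms readout duration and ~3.5x readout-oversampling ratio,
4 coils, seeded measurement noise at 5% of the RMS k-space signal, and
short identical training budgets for the three sampling arms.  See
docs/methods.md for the rationale behind each value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import flow as fl
from . import modl, training
from .model import JointSamplingModel
from .phantom import build_case, build_vessel_case, flow_phantom_spec
from .trajectory import WaveParams, poisson_disc_init


def desk_wave_params(n_grid: int = 32) -> WaveParams:
    """Wave parameterization at desk scale.

    Keeps the full protocol's echo fraction (0.75), readout duration
    (2.7 ms) and readout oversampling ratio while shrinking the matrix;
    the helix radius (4 grid units at 32^3) and 3 cycles keep the
    transverse swirl within hardware limits.
    """
    # keep the full protocol's ~3.5x readout oversampling (675 samples
    # over 192 kx lines): redundant for straight lines, new k-space
    # positions for the helix.
    nro = int(round(3.516 * 0.75 * n_grid))
    return WaveParams(
        r=4.0 * n_grid / 32.0,
        cycles=3,
        echo_fraction=0.75,
        nro=nro,
        dwell=2.7e-3 / nro,
        fov=2.0 * n_grid,
        matrix=n_grid,
        gmax=9.0,
        smax=150.0,
    )


def desk_phase_encodes(n_grid: int = 32, acceleration: float = 11.2) -> int:
    """Phase-encode count matching the full protocol's acceleration."""
    return max(8, int(round(n_grid**2 * 0.75 / acceleration)))


@dataclass
class ComparisonConfig:
    """Study conditions of the three-arm sampling comparison.

    One Adam learning rate for every parameter group, as in the
    full-scale protocol, rescaled to the short budget; seeded measurement
    noise at 5% of the RMS k-space signal — the eps of the acquisition
    model, and the mechanism (noise amplification) wave encoding is
    designed against.  Augmentation is off here (its full-scale ranges
    need far longer budgets to converge through) and is exercised by its
    own tests.
    """

    n_grid: int = 32
    voxel_mm: float = 2.0
    n_train: int = 4
    n_val: int = 2
    n_coils: int = 4
    epochs: int = 6
    lr: float = 0.01
    coord_lr: float | None = None
    n_unrolls: int = 3
    n_layers: int = 3
    features: int = 4
    measurement_noise: float = 0.05  # 5% of RMS k-space signal (SNR 20)


def _single_precision(case):
    """Training runs in complex64 (the operator keeps a float64 oracle path)."""
    case.encoded = case.encoded.astype(np.complex64)
    case.coils.maps = case.coils.maps.astype(np.complex64)
    return case


def sampling_comparison(
    seed: int,
    cfg: ComparisonConfig | None = None,
) -> dict[str, float]:
    """Train wave / no-wave / fixed arms under one identical budget.

    All arms share the Poisson-disc initialization, training cases,
    validation cases and seeds; only the sampling parameterization (and
    which parameters are learnable) differs.  Returns the final
    validation NRMSE per arm.
    """
    cfg = cfg or ComparisonConfig()
    n = cfg.n_grid
    wp = desk_wave_params(n)
    cases = [
        _single_precision(
            build_vessel_case(n, cfg.voxel_mm, seed=100 * seed + s, n_coils=cfg.n_coils)
        )
        for s in range(cfg.n_train)
    ]
    val = [
        _single_precision(
            build_vessel_case(n, cfg.voxel_mm, seed=100 * seed + 50 + s, n_coils=cfg.n_coils)
        )
        for s in range(cfg.n_val)
    ]
    centers = poisson_disc_init(desk_phase_encodes(n), n, seed=seed)
    out = {}
    for mode in ("wave", "no_wave", "fixed"):
        mcfg = modl.MoDLConfig(
            n_unrolls=cfg.n_unrolls, n_layers=cfg.n_layers,
            features=cfg.features, alpha=0.05,
            block_size=2 * n, block_overlap=8,
        )
        tcfg = training.TrainConfig(
            lr=cfg.lr, coord_lr=cfg.coord_lr, epochs=cfg.epochs,
            seed=seed, mode=mode, augment=False,
            measurement_noise=cfg.measurement_noise,
            validate_every_epoch=False,
        )
        model = JointSamplingModel(
            cases, val, wp, mcfg, tcfg, centers=centers
        )
        out[mode] = model.fit().validation_nrmse()
    return out


def sampling_comparison_multi(
    seeds, cfg: ComparisonConfig | None = None
) -> dict[str, np.ndarray]:
    """Run the comparison over several seeds; arrays keyed per arm."""
    per_arm: dict[str, list[float]] = {"wave": [], "no_wave": [], "fixed": []}
    for s in seeds:
        res = sampling_comparison(int(s), cfg)
        for k, v in res.items():
            per_arm[k].append(v)
    return {k: np.asarray(v) for k, v in per_arm.items()}


# ---------------------------------------------------------------------------
# Flow-phantom quantitation
# ---------------------------------------------------------------------------


def phantom_flow_rates(
    n_grid: int = 64,
    voxel_mm: float = 1.0,
    supersample: int = 3,
    noise_sigma: float = 0.0,
    n_sections: int = 5,
) -> dict[str, dict[str, float]]:
    """Decode the three-tube phantom and measure per-tube flow rates.

    Measurements are taken at ``n_sections`` consecutive cross-sections
    perpendicular to each (straight, z-aligned) tube's centerline, using a
    generous geometric mask around the tube so slow edge flow is included.
    Returns, per tube, the mean/SD across sections and the set value.
    """
    spec = flow_phantom_spec(
        n_grid=n_grid, voxel_mm=voxel_mm, supersample=supersample,
        noise_sigma=noise_sigma, n_coils=4,
    )
    case = build_case(spec)
    v = fl.velocity_from_phase(case.encoded, spec.venc)
    ax = (np.arange(n_grid) - n_grid // 2 + 0.5) * voxel_mm
    X, Y = np.meshgrid(ax, ax, indexing="ij")
    z0 = n_grid // 2 - n_sections // 2
    out = {}
    for name, tube, q_true in [
        ("small_tube_1", spec.tubes[0], 0.17),
        ("small_tube_2", spec.tubes[1], 0.15),
        ("large_tube", spec.tubes[2], 1.83),
    ]:
        reg = (
            np.hypot(X - tube.center[0], Y - tube.center[1])
            < tube.radius_mm() + 2 * voxel_mm
        )
        rates = []
        for z in range(z0, z0 + n_sections):
            mask3 = np.zeros((n_grid,) * 3, dtype=bool)
            mask3[:, :, z] = case.vessel_mask[:, :, z] & reg
            cs = fl.axis_cross_section(mask3, 2, z, voxel_mm)
            rates.append(fl.flow_rate(v, cs))
        rates = np.asarray(rates)
        out[name] = {
            "mean_lpm": float(rates.mean()),
            "sd_lpm": float(rates.std(ddof=1)),
            "true_lpm": q_true,
        }
    return out
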