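"""Velocity decoding and quantitative flow statistics.

Decodes 4-point referenced flow encodes into velocity maps, forms the
complex-difference angiogram and its relative-threshold vessel mask, and
computes the agreement statistics used to compare scans: per-section flow
rate, maximum-velocity variability (sigma_vmax, a noise surrogate),
pooled pixelwise linear regression and Bland-Altman limits of agreement,
and the coefficient of variation together with the two-way mixed-effects
consistency ICC, single-measurement form (ICC(3,1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class VelocityVolume:
    """Decoded velocity field, cm/s."""

    v: np.ndarray  # (3, Nx, Ny, Nz)
    venc: float
    source: str = ""


@dataclass
class CrossSection:
    """A planar cross-section through a vessel.

    ``origin`` is a voxel index along the plane normal's axis; the section
    spans the in-plane voxels listed in ``members`` (index arrays).
    """

    normal: np.ndarray  # unit 3-vector
    pixel_area_cm2: float
    members: tuple  # advanced-index tuple selecting member voxels

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=float)
        n = np.linalg.norm(self.normal)
        if not np.isclose(n, 1.0, atol=1e-9):
            raise ValueError("cross-section normal must be unit length")


@dataclass
class AgreementReport:
    """Pooled pixelwise regression + Bland-Altman summary."""

    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple[float, float]
    mean_diff: float
    loa_low: float
    loa_high: float
    n_pixels: int


@dataclass
class ConsistencyReport:
    cv_percent: float
    icc: float
    degenerate: bool = False


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------


def velocity_from_phase(encodes: np.ndarray, venc: float) -> VelocityVolume:
    """v_d = (venc / pi) * angle(m_d * conj(m_0)) for d in {x, y, z}."""
    encodes = np.asarray(encodes)
    ref = encodes[0]
    v = np.stack(
        [(venc / np.pi) * np.angle(encodes[d + 1] * np.conj(ref)) for d in range(3)]
    )
    return VelocityVolume(v=v, venc=venc)


def complex_difference_angiogram(encodes: np.ndarray) -> np.ndarray:
    """CD = sqrt(sum_d |m_d - m_0|^2): bright where flow shifts the phase."""
    encodes = np.asarray(encodes)
    return np.sqrt(np.sum(np.abs(encodes[1:] - encodes[0]) ** 2, axis=0))


def vessel_mask(cd: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Threshold the CD angiogram at a fraction of its maximum."""
    cd = np.asarray(cd)
    return cd >= fraction * cd.max()


# ---------------------------------------------------------------------------
# Flow rate and vmax variability
# ---------------------------------------------------------------------------


def axis_cross_section(
    mask: np.ndarray, axis: int, index: int, voxel_mm: float
) -> CrossSection:
    """Cross-section perpendicular to a principal axis at a voxel index,
    holding every masked voxel in that plane."""
    sel = [slice(None)] * 3
    sel[axis] = index
    plane = mask[tuple(sel)]
    ij = np.nonzero(plane)
    if ij[0].size == 0:
        raise ValueError("cross-section does not intersect the mask")
    idx = [None, None, None]
    idx[axis] = np.full(ij[0].size, index)
    others = [d for d in range(3) if d != axis]
    idx[others[0]], idx[others[1]] = ij
    normal = np.zeros(3)
    normal[axis] = 1.0
    return CrossSection(
        normal=normal,
        pixel_area_cm2=(voxel_mm / 10.0) ** 2,
        members=tuple(idx),
    )


def flow_rate(v: VelocityVolume, cs: CrossSection) -> float:
    """Q in L/min: sum of through-plane velocity times pixel area.

    cm/s * cm^2 = cm^3/s; 1 cm^3/s = 0.06 L/min.
    """
    vn = np.tensordot(cs.normal, v.v[(slice(None),) + cs.members], axes=(0, 0))
    if vn.size == 0:
        raise ValueError("empty cross-section")
    return float(np.sum(vn) * cs.pixel_area_cm2 * 0.06)


def vmax_variability(v: VelocityVolume, sections: list[CrossSection]) -> float:
    """sigma_vmax: sample SD of per-section maximum speed (noise surrogate)."""
    if len(sections) < 2:
        raise ValueError("need at least 2 cross-sections")
    vmax = []
    for cs in sections:
        speed = np.linalg.norm(v.v[(slice(None),) + cs.members], axis=0)
        if speed.size == 0:
            raise ValueError("empty cross-section")
        vmax.append(float(speed.max()))
    return float(np.std(vmax, ddof=1))


# ---------------------------------------------------------------------------
# Agreement statistics
# ---------------------------------------------------------------------------


def pixelwise_agreement(
    vA: VelocityVolume | np.ndarray,
    vB: VelocityVolume | np.ndarray,
    mask: np.ndarray,
    ci: float = 0.95,
) -> AgreementReport:
    """Pooled per-component OLS of B on A plus Bland-Altman limits.

    All three velocity components of every masked voxel are pooled, as in
    clustered scatter comparisons of directional flow.
    """
    a = (vA.v if isinstance(vA, VelocityVolume) else np.asarray(vA))[:, mask].ravel()
    b = (vB.v if isinstance(vB, VelocityVolume) else np.asarray(vB))[:, mask].ravel()
    if int(mask.sum()) < 10:
        raise ValueError("mask too small for agreement statistics (<10 voxels)")
    res = stats.linregress(a, b)
    dof = a.size - 2
    tq = stats.t.ppf(0.5 + ci / 2.0, dof)
    slope_ci = (res.slope - tq * res.stderr, res.slope + tq * res.stderr)
    diff = b - a
    mean_diff = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementReport(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        slope_ci=slope_ci,
        mean_diff=mean_diff,
        loa_low=mean_diff - 1.96 * sd,
        loa_high=mean_diff + 1.96 * sd,
        n_pixels=int(mask.sum()),
    )


def consistency_stats(measurements: np.ndarray) -> ConsistencyReport:
    """CV (%) and ICC(3,1) for a segments x repeats flow-rate table.

    CV pools all values: 100 * SD / mean.  The ICC is the two-way
    mixed-effects, consistency, single-measurement form

        ICC(3,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)

    with MS_R the between-segment and MS_E the residual mean square of the
    two-way ANOVA (segments x repeats).  A table of identical values is
    degenerate: CV = 0 and ICC reported as 1 with the ``degenerate`` flag.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2:
        raise ValueError("measurements must be a 2D segments x repeats table")
    n, k = x.shape
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean flow table")
    cv = 100.0 * x.std(ddof=1) / mean
    if np.allclose(x, x.flat[0]):
        return ConsistencyReport(cv_percent=0.0, icc=1.0, degenerate=True)
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - mean) ** 2)
    ss_cols = n * np.sum((col_means - mean) ** 2)
    ss_total = np.sum((x - mean) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)
    return ConsistencyReport(cv_percent=float(cv), icc=float(icc))
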