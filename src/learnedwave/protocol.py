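"""Scan-protocol arithmetic for 3D phase-contrast acquisitions.

A steady-state 3D PC scan acquires ``n_phase_encodes`` readouts per flow
encode and ``n_flow_encodes`` flow encodes (one reference plus three
velocity-encoded acquisitions for 4-point encoding), one readout per TR.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ScanProtocol:
    """Timing and sampling parameters of a 3D PC-MRI protocol.

    Parameters
    ----------
    tr : float
        Repetition time in seconds.
    fov_mm : float
        Field of view per axis (isotropic), mm.
    resolution_mm : float
        Nominal isotropic voxel size, mm.
    n_phase_encodes : int
        Number of phase-encode positions (readouts) per flow encode.
    n_flow_encodes : int
        Flow-encoding points (4 = reference + three orthogonal encodes).
    echo_fraction : float
        Acquired fraction of the readout (frequency-encode) direction.
    """

    tr: float
    fov_mm: float
    resolution_mm: float
    n_phase_encodes: int
    n_flow_encodes: int = 4
    echo_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if not 0.5 < self.echo_fraction <= 1.0:
            raise ValueError("echo_fraction must lie in (0.5, 1]")
        if self.n_phase_encodes < 1 or self.n_flow_encodes < 1:
            raise ValueError("encode counts must be positive")

    @property
    def matrix(self) -> int:
        """Reconstruction matrix size per axis."""
        return round(self.fov_mm / self.resolution_mm)

    def scan_time_seconds(self) -> float:
        """Total scan time: one TR per phase encode per flow encode."""
        return self.tr * self.n_phase_encodes * self.n_flow_encodes

    def scan_time_minutes(self) -> float:
        return self.scan_time_seconds() / 60.0

    def acceleration_factor(self) -> float:
        """Undersampling factor relative to full Cartesian phase encoding.

        Computed as ``matrix**2 * echo_fraction / n_phase_encodes``: the
        fully sampled Cartesian acquisition needs one phase encode per
        (ky, kz) grid point, and the partial echo counts as a further
        reduction of acquired data by the echo fraction.
        """
        return self.matrix**2 * self.echo_fraction / self.n_phase_encodes


def accelerated_protocol() -> ScanProtocol:
    """The accelerated learned-sampling protocol (TR 7.7 ms, 4385 encodes)."""
    return ScanProtocol(
        tr=7.7e-3,
        fov_mm=220.0,
        resolution_mm=0.86,
        n_phase_encodes=4385,
        n_flow_encodes=4,
        echo_fraction=0.75,
    )


def reference_protocol() -> ScanProtocol:
    """The reference 3D radial protocol (TR 7.7 ms, 11000 spokes)."""
    return ScanProtocol(
        tr=7.7e-3,
        fov_mm=220.0,
        resolution_mm=0.86,
        n_phase_encodes=11000,
        n_flow_encodes=4,
        echo_fraction=0.75,
    )
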