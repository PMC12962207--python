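"""HDF5 container schemas and NIfTI export.

One HDF5 layout is shared across the package (complex data and ragged
trajectory shapes rule out NIfTI as the primary container):

trajectory file:   /coords (NPE, NRO, 3) float64, /kyc /kzc /sr /theta,
                   attrs: meta (JSON string with the wave parameterization)
phantom case file: /encoded (4, N, N, N) complex64, /coils, /magnitude,
                   /velocity_truth (3, N, N, N), /mask, attrs: spec (JSON)
checkpoint file:   /weights/layer{i}/{X,Y,bias_re,bias_im}, /alpha,
                   /kyc /kzc /sr /theta, attrs: config (JSON)
reconstruction:    /image (N, N, N) complex64

NIfTI is used only to export real-valued volumes (magnitude, speed).
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import nibabel as nib
import numpy as np

from . import modl
from .encoding import CoilSensitivities
from .phantom import PhantomCase, PhantomSpec, Tube
from .trajectory import HelixSet, Trajectory, WaveParams


class SchemaError(ValueError):
    """The file does not match the expected HDF5 layout."""


def _require(f: h5py.File, names: list[str], kind: str) -> None:
    missing = [n for n in names if n not in f]
    if missing:
        raise SchemaError(f"{kind} file is missing datasets: {missing}")


# ---------------------------------------------------------------------------
# Trajectory
# ---------------------------------------------------------------------------


def save_trajectory(path: str, traj: Trajectory) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("coords", data=traj.coords)
        hs = traj.helix_set
        if hs is not None:
            for name in ("kyc", "kzc", "sr", "theta"):
                f.create_dataset(name, data=getattr(hs, name))
        meta = {
            k: (v.tolist() if isinstance(v, np.ndarray) else v)
            for k, v in traj.meta.items()
        }
        meta["mode"] = traj.mode
        meta["wave_params"] = dataclasses.asdict(traj.wave_params)
        f.attrs["meta"] = json.dumps(meta)


def load_trajectory(path: str) -> Trajectory:
    try:
        with h5py.File(path, "r") as f:
            _require(f, ["coords"], "trajectory")
            if "meta" not in f.attrs:
                raise SchemaError("trajectory file lacks the meta attribute")
            meta = json.loads(f.attrs["meta"])
            wp = WaveParams(**meta.pop("wave_params"))
            mode = meta.pop("mode")
            hs = None
            if "kyc" in f:
                hs = HelixSet(
                    kyc=f["kyc"][:], kzc=f["kzc"][:],
                    sr=f["sr"][:], theta=f["theta"][:],
                )
            return Trajectory(
                coords=f["coords"][:], mode=mode, wave_params=wp,
                helix_set=hs, meta=meta,
            )
    except OSError as e:
        raise SchemaError(f"not a readable HDF5 file: {e}") from e


# ---------------------------------------------------------------------------
# Phantom cases
# ---------------------------------------------------------------------------


def _spec_to_json(spec: PhantomSpec) -> str:
    d = dataclasses.asdict(spec)
    for tube in d["tubes"]:
        if tube["control_points"] is not None:
            tube["control_points"] = np.asarray(tube["control_points"]).tolist()
    return json.dumps(d)


def _spec_from_json(s: str) -> PhantomSpec:
    d = json.loads(s)
    tubes = []
    for t in d.pop("tubes"):
        cp = t.pop("control_points")
        tubes.append(Tube(**t, control_points=None if cp is None else np.asarray(cp)))
    return PhantomSpec(tubes=tubes, **d)


def save_phantom_case(path: str, case: PhantomCase) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("encoded", data=case.encoded.astype(np.complex64))
        f.create_dataset("coils", data=case.coils.maps.astype(np.complex64))
        f.create_dataset("magnitude", data=case.magnitude)
        f.create_dataset("velocity_truth", data=case.velocity)
        f.create_dataset("mask", data=case.vessel_mask)
        f.attrs["spec"] = _spec_to_json(case.spec)


def load_phantom_case(path: str) -> PhantomCase:
    try:
        with h5py.File(path, "r") as f:
            _require(
                f, ["encoded", "coils", "magnitude", "velocity_truth", "mask"],
                "phantom case",
            )
            spec = _spec_from_json(f.attrs["spec"])
            return PhantomCase(
                spec=spec,
                magnitude=f["magnitude"][:],
                velocity=f["velocity_truth"][:],
                vessel_mask=f["mask"][:].astype(bool),
                encoded=f["encoded"][:].astype(np.complex128),
                coils=CoilSensitivities(maps=f["coils"][:].astype(np.complex128)),
            )
    except OSError as e:
        raise SchemaError(f"not a readable HDF5 file: {e}") from e


# ---------------------------------------------------------------------------
# Model checkpoints and reconstructions
# ---------------------------------------------------------------------------


def save_checkpoint(path: str, state, extra: dict | None = None) -> None:
    """Persist a TrainState (learnables + config)."""
    with h5py.File(path, "w") as f:
        g = f.create_group("weights")
        for i, layer in enumerate(state.weights):
            lg = g.create_group(f"layer{i}")
            lg.create_dataset("X", data=layer.X)
            lg.create_dataset("Y", data=layer.Y)
            lg.create_dataset("bias_re", data=layer.bias_re)
            lg.create_dataset("bias_im", data=layer.bias_im)
        f.create_dataset("alpha", data=np.asarray(state.alpha))
        for name in ("kyc", "kzc", "sr", "theta"):
            f.create_dataset(name, data=getattr(state.hs, name))
        config = {
            "mode": state.mode,
            "wave_params": dataclasses.asdict(state.wp),
            "modl": dataclasses.asdict(state.modl_cfg),
            "history": state.history,
        }
        if extra:
            config.update(extra)
        f.attrs["config"] = json.dumps(config)


def load_checkpoint(path: str):
    from .training import TrainState

    try:
        with h5py.File(path, "r") as f:
            _require(f, ["weights", "alpha", "kyc"], "checkpoint")
            config = json.loads(f.attrs["config"])
            layers = []
            g = f["weights"]
            for i in range(len(g)):
                lg = g[f"layer{i}"]
                layers.append(
                    modl.ComplexConvLayer(
                        X=lg["X"][:], Y=lg["Y"][:],
                        bias_re=lg["bias_re"][:], bias_im=lg["bias_im"][:],
                    )
                )
            hs = HelixSet(
                kyc=f["kyc"][:], kzc=f["kzc"][:], sr=f["sr"][:], theta=f["theta"][:]
            )
            return TrainState(
                wp=WaveParams(**config["wave_params"]),
                hs=hs,
                weights=layers,
                alpha=float(f["alpha"][()]),
                mode=config["mode"],
                modl_cfg=modl.MoDLConfig(**config["modl"]),
                history=config.get("history", {"train": [], "val": []}),
            )
    except OSError as e:
        raise SchemaError(f"not a readable HDF5 file: {e}") from e


def save_recon(path: str, image: np.ndarray) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("image", data=np.asarray(image).astype(np.complex64))


def load_recon(path: str) -> np.ndarray:
    try:
        with h5py.File(path, "r") as f:
            _require(f, ["image"], "reconstruction")
            return f["image"][:].astype(np.complex128)
    except OSError as e:
        raise SchemaError(f"not a readable HDF5 file: {e}") from e


def export_nifti(path: str, volume: np.ndarray, voxel_mm: float = 1.0) -> None:
    """Export a real-valued volume (magnitude, speed, ...) as NIfTI."""
    vol = np.asarray(volume)
    if np.iscomplexobj(vol):
        raise ValueError("NIfTI export is for real-valued volumes; take abs() first")
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)
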