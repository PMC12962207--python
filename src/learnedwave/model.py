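"""Model/results interface to the joint sampling + reconstruction learner.

``JointSamplingModel`` is constructed from data (training/validation
cases) and configuration; ``fit()`` runs the end-to-end optimization and
returns a ``JointSamplingResults`` carrying the learned trajectory
parameters, denoiser weights, step size, loss history, and convenience
methods (``summary()``, ``reconstruct()``, ``save()``).
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import modl, training
from .encoding import EncodingOperator
from .trajectory import WaveParams, poisson_disc_init


class JointSamplingModel:
    """Joint sampling/reconstruction model to be fitted to volume data.

    Parameters
    ----------
    train_cases, val_cases : sequences of objects with ``.volume`` (complex
        ndarray) and ``.coils`` (CoilSensitivities), e.g. PhantomCase.
    wave_params : WaveParams
        Shared helix parameterization (grid size, radius, cycles, ...).
    modl_config : MoDLConfig
    train_config : TrainConfig
        Mode ("wave" | "no_wave" | "fixed"), optimizer and augmentation.
    n_phase_encodes : int
        Number of phase-encode centers (ignored when ``centers`` given).
    centers : optional (kyc, kzc)
        Shared Poisson-disc initialization; pass the same draw to wave and
        no-wave models for a controlled comparison.
    """

    def __init__(
        self,
        train_cases,
        val_cases,
        wave_params: WaveParams,
        modl_config: modl.MoDLConfig,
        train_config: training.TrainConfig,
        n_phase_encodes: int | None = None,
        centers=None,
    ):
        if not train_cases:
            raise ValueError("need at least one training case")
        self.train_cases = list(train_cases)
        self.val_cases = list(val_cases)
        self.wave_params = wave_params
        self.modl_config = modl_config
        self.train_config = train_config
        if centers is None:
            if n_phase_encodes is None:
                raise ValueError("give n_phase_encodes or centers")
            centers = poisson_disc_init(
                n_phase_encodes, wave_params.matrix, seed=train_config.seed
            )
        self.centers = centers

    def fit(self) -> "JointSamplingResults":
        state = training.train(
            self.train_cases,
            self.train_config,
            self.wave_params,
            self.modl_config,
            self.centers,
            val_cases=self.val_cases,
        )
        return JointSamplingResults(self, state)


class JointSamplingResults:
    """Fitted learnables plus diagnostics."""

    def __init__(self, model: JointSamplingModel, state: training.TrainState):
        self.model = model
        self.state = state

    # -- accessors ---------------------------------------------------------

    @property
    def helix_set(self):
        return self.state.hs

    @property
    def alpha(self) -> float:
        return self.state.alpha

    @property
    def weights(self):
        return self.state.weights

    @property
    def history(self) -> dict:
        return self.state.history

    def trajectory(self):
        return self.state.trajectory()

    # -- evaluation --------------------------------------------------------

    def validation_nrmse(self) -> float:
        if not self.model.val_cases:
            raise ValueError("model has no validation cases")
        return training.validate(
            self.model.val_cases, self.state, self.model.train_config
        )

    def reconstruct(self, case_or_kspace, coils=None) -> np.ndarray:
        """Reconstruct a case (simulating its k-space) or raw k-space data."""
        cfg = self.model.train_config
        traj = self.trajectory()
        if hasattr(case_or_kspace, "coils"):
            coils = case_or_kspace.coils
            op = EncodingOperator(
                coils, traj, engine=cfg.engine,
                oversamp=cfg.nufft_oversamp, width=cfg.nufft_width,
            )
            y = op.forward(case_or_kspace.volume)
        else:
            if coils is None:
                raise ValueError("raw k-space needs coil maps")
            op = EncodingOperator(
                coils, traj, engine=cfg.engine,
                oversamp=cfg.nufft_oversamp, width=cfg.nufft_width,
            )
            y = np.asarray(case_or_kspace).reshape(op.n_coils, -1)
        return modl.unrolled_recon(
            y, op, self.state.modl_cfg, self.state.weights, self.state.alpha
        )

    def reconstruct_encodes(self, encodes, coils) -> np.ndarray:
        """Reconstruct all four flow encodes of a phantom case."""
        out = np.empty_like(np.asarray(encodes))
        cfg = self.model.train_config
        traj = self.trajectory()
        op = EncodingOperator(
            coils, traj, engine=cfg.engine,
            oversamp=cfg.nufft_oversamp, width=cfg.nufft_width,
        )
        for e in range(len(encodes)):
            y = op.forward(np.asarray(encodes[e]))
            out[e] = modl.unrolled_recon(
                y, op, self.state.modl_cfg, self.state.weights, self.state.alpha
            )
        return out

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        st = self.state
        wp = st.wp
        lines = [
            "Joint sampling + MoDL reconstruction fit",
            "=" * 44,
            f"mode:                 {st.mode}",
            f"grid / FOV:           {wp.matrix}^3 / {wp.fov:.0f} mm",
            f"phase encodes:        {st.hs.npe}",
            f"readout samples:      {wp.nro}  (echo fraction {wp.echo_fraction})",
            f"helix radius r:       {wp.r:.3g} grid units, {wp.cycles} cycles",
            f"denoiser parameters:  {modl.parameter_count(st.modl_cfg)}",
            f"unrolls:              {st.modl_cfg.n_unrolls}",
            f"step size alpha:      {st.alpha:.4g}",
            f"sr range:             [{st.hs.sr.min():.3f}, {st.hs.sr.max():.3f}]",
            f"epochs:               {len(st.history['train'])}",
        ]
        if st.history["train"]:
            lines.append(
                f"train NRMSE:          {st.history['train'][0]:.4f} -> "
                f"{st.history['train'][-1]:.4f}"
            )
        if st.history["val"]:
            lines.append(f"val NRMSE (final):    {st.history['val'][-1]:.4f}")
        return "\n".join(lines)

    def save(self, path: str) -> None:
        from . import io as lwio

        lwio.save_checkpoint(path, self.state)

    @classmethod
    def load(cls, path: str, model: JointSamplingModel | None = None):
        from . import io as lwio

        state = lwio.load_checkpoint(path)
        if model is None:
            cfg = training.TrainConfig(mode=state.mode)
            model = JointSamplingModel.__new__(JointSamplingModel)
            model.train_cases, model.val_cases = [], []
            model.wave_params = state.wp
            model.modl_config = state.modl_cfg
            model.train_config = cfg
            model.centers = (state.hs.kyc, state.hs.kzc)
        return cls(model, state)
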