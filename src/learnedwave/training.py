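"""End-to-end joint optimization of sampling and reconstruction.

Each training step simulates multi-coil k-space from a (phase- and
noise-augmented) ground-truth volume through the current trajectory,
reconstructs it with the unrolled network, and takes one Adam step on the
NRMSE loss with respect to *all* learnables: phase-encode centers
(kyc, kzc), helix radius scaling sr and rotation theta (wave mode only),
the data-consistency step size alpha, and the denoiser weights.  After
every step sr is projected back into (0, 1] and centers are clamped so
the whole helix stays inside the k-space box; hardware limits are
re-enforced by radius down-scaling.

The loss is the printed ratio of summed squares
``sum|m - m_hat|^2 / sum|m|^2`` (no square root).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import autodiff as ad
from . import modl
from .encoding import CoilSensitivities, EncodingOperator, add_noise
from .trajectory import (
    HelixSet,
    WaveParams,
    build_trajectory,
    enforce_hardware,
)


@dataclass
class TrainConfig:
    """Optimizer and augmentation settings."""

    lr: float = 1e-3
    coord_lr: float | None = None  # sampling-parameter group; defaults to lr
    weight_decay: float = 1e-3
    epochs: int = 10
    seed: int = 0
    phase_coeff_range: tuple[float, float] = (-10.0, 10.0)
    scale_range: tuple[float, float] = (0.3, 3.0)
    noise_factor_range: tuple[float, float] = (0.5, 1.5)
    mode: str = "wave"  # wave | no_wave | fixed
    engine: str = "nufft"
    nufft_oversamp: float = 1.25
    nufft_width: int = 4
    use_checkpoint: bool = False
    augment: bool = True
    base_noise_sigma: float = 0.0
    validate_every_epoch: bool = True
    #: measurement-noise level of the simulated acquisition y = A m + eps,
    #: as a fraction of the RMS k-space signal (seeded; applied in both
    #: training and validation, independent of the augmentation scheme).
    measurement_noise: float = 0.0

    def __post_init__(self) -> None:
        if self.lr < 0:
            raise ValueError("lr must be non-negative")
        for rng_pair in (self.phase_coeff_range, self.scale_range, self.noise_factor_range):
            if rng_pair[0] > rng_pair[1]:
                raise ValueError("augmentation ranges must be ordered")
        if self.mode not in ("wave", "no_wave", "fixed"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class AugmentSpec:
    """One draw of the per-case augmentation parameters."""

    a1: float
    a2: float
    a3: float
    a4: float
    b: float
    n: float


def draw_augment(rng: np.random.Generator, cfg: TrainConfig) -> AugmentSpec:
    lo, hi = cfg.phase_coeff_range
    a = rng.uniform(lo, hi, size=4)
    b = rng.uniform(*cfg.scale_range)
    n = rng.uniform(*cfg.noise_factor_range)
    return AugmentSpec(a1=a[0], a2=a[1], a3=a[2], a4=a[3], b=b, n=n)


def augment_phase(m: np.ndarray, spec: AugmentSpec) -> np.ndarray:
    """m_aug = b * m * exp(2*pi*i * (a1 x + a2 y + a3 z + a4)).

    Spatial coordinates are normalized to [-0.5, 0.5) per axis, so a
    coefficient of 10 means ten phase cycles across the FOV.
    """
    shape = m.shape
    axes = [(np.arange(n) - n // 2) / n for n in shape]
    phi = (
        spec.a1 * axes[0][:, None, None]
        + spec.a2 * axes[1][None, :, None]
        + spec.a3 * axes[2][None, None, :]
        + spec.a4
    )
    return spec.b * m * np.exp(2j * np.pi * phi)


_MEDIAN_ABS_GAUSS = 0.6744897501960817  # Phi^{-1}(0.75)


def estimate_noise_sigma(kdata: np.ndarray, coords: np.ndarray, n_grid: int):
    """Per-component noise level from the edge of k-space.

    Samples with max-norm radius above 0.9 * N/2 form the edge shell; the
    median absolute value of the real/imaginary parts there, divided by
    Phi^{-1}(0.75), estimates the Gaussian sigma of each component.
    """
    coords = np.asarray(coords).reshape(-1, 3)
    radius = np.max(np.abs(coords), axis=1)
    shell = radius > 0.9 * (n_grid / 2.0)
    if not np.any(shell):
        raise ValueError("no samples in the k-space edge shell")
    vals = np.asarray(kdata).reshape(-1, coords.shape[0])[:, shell]
    sigma_re = float(np.median(np.abs(vals.real)) / _MEDIAN_ABS_GAUSS)
    sigma_im = float(np.median(np.abs(vals.imag)) / _MEDIAN_ABS_GAUSS)
    return sigma_re, sigma_im


def augment_noise(
    kdata: np.ndarray, n: float, sigma_re: float, sigma_im: float, seed: int
) -> np.ndarray:
    """Add complex Gaussian noise of per-component std n*sigma_{re,im}."""
    rng = np.random.default_rng(seed)
    kdata = np.asarray(kdata)
    return (
        kdata
        + n * sigma_re * rng.standard_normal(kdata.shape)
        + 1j * n * sigma_im * rng.standard_normal(kdata.shape)
    )


def nrmse_loss(m_hat: np.ndarray, m: np.ndarray) -> float:
    """sum|m - m_hat|^2 / sum|m|^2 (ratio of summed squares, as printed)."""
    denom = float(np.sum(np.abs(m) ** 2))
    if denom == 0:
        raise ValueError("all-zero reference image")
    return float(np.sum(np.abs(np.asarray(m_hat) - np.asarray(m)) ** 2) / denom)


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------


class Adam:
    """Adam with L2 weight decay added to the gradient (framework default)."""

    def __init__(
        self, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0,
        lr_overrides: dict[str, float] | None = None,
    ):
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.wd = weight_decay
        self.lr_overrides = lr_overrides or {}
        self.state: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        for name, p in params.items():
            g = np.asarray(grads[name], dtype=float) + self.wd * p
            if name not in self.state:
                self.state[name] = (np.zeros_like(p), np.zeros_like(p))
            m, v = self.state[name]
            m = self.b1 * m + (1 - self.b1) * g
            v = self.b2 * v + (1 - self.b2) * g * g
            self.state[name] = (m, v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            lr = self.lr_overrides.get(name, self.lr)
            p -= lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Training state and loop
# ---------------------------------------------------------------------------


@dataclass
class TrainState:
    """Mutable bundle of all learnables plus bookkeeping."""

    wp: WaveParams
    hs: HelixSet
    weights: list
    alpha: float
    mode: str
    modl_cfg: modl.MoDLConfig = field(default_factory=modl.MoDLConfig)
    alpha_max: float = np.inf  # stability bound 0.8/||A^H A|| set at init
    history: dict = field(default_factory=lambda: {"train": [], "val": []})

    def trajectory(self):
        """Fixed baselines keep straight readouts like the no-wave arm."""
        traj_mode = "wave" if self.mode == "wave" else "no_wave"
        return build_trajectory(self.wp, self.hs, mode=traj_mode)


def _center_bound(state: TrainState) -> np.ndarray:
    """Per-helix bound so center + helix radius stays inside [-N/2, N/2)."""
    half = state.wp.matrix / 2.0 - 1e-3
    if state.mode != "wave":  # straight readouts: no transverse excursion
        return np.full(state.hs.npe, half)
    return half - state.hs.sr * state.wp.r


def project_constraints(state: TrainState) -> None:
    """Clamp sr into (0, 1], keep helices inside the box, keep the DC step
    size inside its non-expansiveness bound, re-check hardware."""
    state.alpha = float(np.clip(state.alpha, 1e-4, state.alpha_max))
    hs = state.hs
    hs.sr[:] = np.clip(hs.sr, 1e-3, 1.0)
    bound = _center_bound(state)
    hs.kyc[:] = np.clip(hs.kyc, -bound, bound)
    hs.kzc[:] = np.clip(hs.kzc, -bound, bound)
    if state.mode == "wave":
        traj = build_trajectory(state.wp, hs, mode="wave")
        constrained = enforce_hardware(traj, state.wp)
        if constrained.helix_set is not None:
            state.hs = constrained.helix_set


def init_state(
    wp: WaveParams,
    centers: tuple[np.ndarray, np.ndarray],
    modl_cfg: modl.MoDLConfig,
    mode: str,
    seed: int,
    coils: CoilSensitivities | None = None,
    engine: str = "nufft",
) -> TrainState:
    """Build the initial training state from shared Poisson-disc centers."""
    kyc, kzc = centers
    hs_mode = "wave" if mode == "wave" else "no_wave"
    hs = HelixSet.from_centers(kyc.copy(), kzc.copy(), mode=hs_mode)
    weights = modl.init_denoiser(modl_cfg, seed=seed)
    state = TrainState(
        wp=wp, hs=hs, weights=weights, alpha=modl_cfg.alpha,
        mode=mode, modl_cfg=modl_cfg,
    )
    project_constraints(state)
    if coils is not None:
        op = EncodingOperator(coils, state.trajectory(), engine=engine)
        state.alpha = modl.suggest_alpha(op, seed=seed)  # 0.5 / L
        state.alpha_max = 1.6 * state.alpha  # 0.8 / L
    return state


def _coords_var(state: TrainState, learn_coords: bool):
    """Leaves + coordinate Var for the current mode."""
    hs = state.hs
    if state.mode == "wave":
        vk = ad.leaf(hs.kyc.copy(), learn_coords, name="kyc")
        vz = ad.leaf(hs.kzc.copy(), learn_coords, name="kzc")
        vs = ad.leaf(hs.sr.copy(), learn_coords, name="sr")
        vt = ad.leaf(hs.theta.copy(), learn_coords, name="theta")
        coords = ad.wave_coords_op(vk, vz, vs, vt, state.wp, hs)
        return {"kyc": vk, "kzc": vz, "sr": vs, "theta": vt}, coords
    vk = ad.leaf(hs.kyc.copy(), learn_coords, name="kyc")
    vz = ad.leaf(hs.kzc.copy(), learn_coords, name="kzc")
    coords = ad.straight_coords_op(vk, vz, state.wp, hs)
    return {"kyc": vk, "kzc": vz}, coords


def training_step(
    state: TrainState,
    case,
    cfg: TrainConfig,
    opt: Adam,
    step_seed: int,
) -> float:
    """One augmented forward/backward/update pass on a single case.

    ``case`` provides ``.volume`` (complex ndarray) and ``.coils``.
    Returns the loss value.
    """
    rng = np.random.default_rng(step_seed)
    m = case.volume
    if cfg.augment:
        spec = draw_augment(rng, cfg)
        m = augment_phase(m, spec)
    coils = case.coils

    # one operator per coordinate array: every unroll (and its backward)
    # reuses the cached interpolation tables.
    op_cache: list = []

    def make_op(c):
        for ref, op in op_cache:
            if ref is c:
                return op
        op = EncodingOperator(
            coils, c, engine=cfg.engine,
            oversamp=cfg.nufft_oversamp, width=cfg.nufft_width,
        )
        op_cache.append((c, op))
        return op

    learn_coords = state.mode != "fixed" and cfg.lr > 0
    params, coords = _coords_var(state, learn_coords)
    m_const = ad.constant(m)
    y = ad.nufft_forward_op(m_const, coords, make_op)
    if cfg.measurement_noise > 0:
        sigma = cfg.measurement_noise * float(
            np.sqrt(np.mean(np.abs(y.value) ** 2))
        )
        eps = add_noise(
            np.zeros_like(y.value), sigma, seed=int(rng.integers(2**31 - 1))
        )
        y = ad.add(y, ad.constant(eps))
    if cfg.augment:
        n_grid = state.wp.matrix
        try:
            s_re, s_im = estimate_noise_sigma(y.value, coords.value, n_grid)
        except ValueError:
            s_re = s_im = 0.0
        if cfg.base_noise_sigma > 0:
            s_re = s_im = cfg.base_noise_sigma
        noisy = augment_noise(
            y.value, spec.n, s_re, s_im, seed=int(rng.integers(2**31 - 1))
        )
        y = ad.add(y, ad.constant(noisy - y.value))
    weight_vars = modl.weights_to_vars(state.weights, requires_grad=True)
    alpha_var = ad.leaf(np.asarray(state.alpha), True, name="alpha")
    m_hat = modl.unrolled_recon_op(
        y, coords, make_op, state.modl_cfg, weight_vars, alpha_var,
        use_checkpoint=cfg.use_checkpoint,
    )
    loss = ad.nrmse(m_hat, m_const)
    if not np.isfinite(loss.value):
        raise FloatingPointError("NaN/inf training loss; aborting")
    ad.backward(loss)

    flat_params: dict[str, np.ndarray] = {}
    flat_grads: dict[str, np.ndarray] = {}
    if learn_coords:
        for name, var in params.items():
            flat_params[name] = getattr(state.hs, name)
            flat_grads[name] = (
                var.grad if var.grad is not None else np.zeros_like(var.value)
            )
    alpha_arr = np.asarray([state.alpha])
    flat_params["alpha"] = alpha_arr
    flat_grads["alpha"] = np.asarray(
        [float(alpha_var.grad) if alpha_var.grad is not None else 0.0]
    )
    for li, ((vX, vY, vbr, vbi), layer) in enumerate(
        zip(weight_vars, state.weights)
    ):
        for tag, var, arr in (
            ("X", vX, layer.X), ("Y", vY, layer.Y),
            ("br", vbr, layer.bias_re), ("bi", vbi, layer.bias_im),
        ):
            flat_params[f"w{li}.{tag}"] = arr
            flat_grads[f"w{li}.{tag}"] = (
                var.grad if var.grad is not None else np.zeros_like(arr)
            )
    opt.step(flat_params, flat_grads)
    state.alpha = float(alpha_arr[0])
    project_constraints(state)
    return float(loss.value)


def validate(cases, state: TrainState, cfg: TrainConfig) -> float:
    """Mean NRMSE over cases: deterministic, no augmentation.

    Measurement noise (the eps of the acquisition model), when configured,
    is drawn from a fixed per-case seed so repeated calls agree exactly.
    """
    losses = []
    traj = state.trajectory()
    for idx, case in enumerate(cases):
        op = EncodingOperator(
            case.coils, traj, engine=cfg.engine,
            oversamp=cfg.nufft_oversamp, width=cfg.nufft_width,
        )
        y = op.forward(case.volume)
        if cfg.measurement_noise > 0:
            sigma = cfg.measurement_noise * float(np.sqrt(np.mean(np.abs(y) ** 2)))
            y = add_noise(y, sigma, seed=977 * (idx + 1))
        m_hat = modl.unrolled_recon(y, op, state.modl_cfg, state.weights, state.alpha)
        losses.append(nrmse_loss(m_hat, case.volume))
    return float(np.mean(losses))


def train(
    cases,
    cfg: TrainConfig,
    wp: WaveParams,
    modl_cfg: modl.MoDLConfig,
    centers: tuple[np.ndarray, np.ndarray],
    val_cases=(),
) -> TrainState:
    """Full training loop; fully seeded and reproducible.

    Per epoch, all cases are visited once in a random order with no
    gradient accumulation; validation loss is recorded per epoch.
    """
    rng = np.random.default_rng(cfg.seed)
    state = init_state(
        wp, centers, modl_cfg,
        mode=cfg.mode, seed=cfg.seed,
        coils=cases[0].coils if cases else None,
        engine=cfg.engine,
    )
    state.modl_cfg = replace(modl_cfg, alpha=state.alpha)
    overrides = None
    if cfg.coord_lr is not None:
        overrides = {k: cfg.coord_lr for k in ("kyc", "kzc", "sr", "theta")}
    opt = Adam(lr=cfg.lr, weight_decay=cfg.weight_decay, lr_overrides=overrides)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(cases))
        epoch_losses = []
        for idx in order:
            step_seed = int(rng.integers(2**31 - 1))
            epoch_losses.append(
                training_step(state, cases[idx], cfg, opt, step_seed)
            )
        state.history["train"].append(float(np.mean(epoch_losses)))
        if val_cases and (cfg.validate_every_epoch or epoch == cfg.epochs - 1):
            state.history["val"].append(validate(val_cases, state, cfg))
    return state
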