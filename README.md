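# learnedwave

Jointly learned 3D non-Cartesian sampling with wave encoding and unrolled
model-based reconstruction for neurovascular phase-contrast MRI, with
synthetic 4-point flow phantoms and quantitative flow evaluation.

## The problem

3D phase-contrast MRI (time-averaged 4D flow) measures blood velocity but
needs long scans: four flow encodes at high spatial resolution. Heavy
undersampling makes the choice of *where* to sample k-space and *how* to
reconstruct inseparable. This package implements the data-driven answer:
treat the sampling trajectory itself as a learnable object and optimize
it jointly with the reconstruction network.

Each readout is a helix ("wave" encoding): constant kx gradient with
sinusoidal ky/kz gradients. A shared base helix (radius r, cycles C,
echo fraction ef) is placed at learnable phase-encode centers
(kyc, kzc), with learnable per-readout radius scaling sr ∈ (0, 1] and
rotation θ:

    ky[j,i] = sr[j] · r · sin(t[i] + θ[j]) + kyc[j]
    kz[j,i] = sr[j] · r · cos(t[i] + θ[j]) + kzc[j]

The acquisition model is y = C F S m + ε (coil maps, 3D NUFFT at the
trajectory's off-grid coordinates, noise). Reconstruction is MoDL: a
fixed number of unrolls alternating the data-consistency step
z = m − 2α·Aᴴ(Am − y) with a learned fully complex ResNet denoiser
(complex convolutions W∗d = (X∗a − Y∗b) + i(Y∗a + X∗b), CReLU). All
learnables — sampling coordinates, wave parameters, step size α, and
denoiser weights — are trained end-to-end on the image-domain loss
Σ|m − m̂|²/Σ|m|², with the backward pass through the NUFFT using exact
analytic coordinate Jacobians (Wirtinger calculus) instead of
differentiating the gridding interpolation kernel.

Intended users: MRI acquisition/reconstruction researchers who want a
transparent, fully tested CPU reference of learned non-Cartesian
sampling — every operator, gradient and statistic is validated against
independent oracles.

## Worked example

Fit a small joint model on synthetic vessel volumes, then quantify a
three-tube flow phantom with it:

```python
from learnedwave import JointSamplingModel, MoDLConfig, TrainConfig
from learnedwave.experiments import desk_wave_params, desk_phase_encodes
from learnedwave.phantom import build_vessel_case, build_case, flow_phantom_spec
from learnedwave.trajectory import poisson_disc_init
from learnedwave import flow as fl

n = 16
train_cases = [build_vessel_case(n, 2.0, seed=s, n_coils=2) for s in range(3)]
val_cases = [build_vessel_case(n, 2.0, seed=50, n_coils=2)]
model = JointSamplingModel(
    train_cases, val_cases,
    wave_params=desk_wave_params(n),
    modl_config=MoDLConfig(n_unrolls=2, n_layers=3, features=2,
                           alpha=0.05, block_size=32, block_overlap=4),
    train_config=TrainConfig(lr=0.01, epochs=4, seed=0, mode="wave",
                             augment=False, measurement_noise=0.05),
    centers=poisson_disc_init(desk_phase_encodes(n), n, seed=0),
)
results = model.fit()
print(results.summary())
```

prints

```
Joint sampling + MoDL reconstruction fit
============================================
mode:                 wave
grid / FOV:           16^3 / 32 mm
phase encodes:        17
readout samples:      42  (echo fraction 0.75)
helix radius r:       2 grid units, 3 cycles
denoiser parameters:  442
unrolls:              2
step size alpha:      0.412
sr range:             [0.885, 1.000]
epochs:               4
train NRMSE:          0.4034 -> 0.1615
val NRMSE (final):    0.1709
```

The training loss (the Σ|m − m̂|²/Σ|m|² ratio) drops from 0.40 to 0.16
over four epochs; some helices were scaled down (sr < 1) while staying
inside the gradient-hardware limits, and the data-consistency step size
settled at 0.41 (initialized at 0.5/‖AᴴA‖ by power iteration).
Reconstructing the three-tube flow phantom's four encodes with the
fitted model and decoding velocity (v = Venc/π · ∠ m_d m₀*):

```python
phantom = build_case(flow_phantom_spec(n_grid=n, voxel_mm=2.0, n_coils=2))
recon = results.reconstruct_encodes(phantom.encoded, phantom.coils)
v = fl.velocity_from_phase(recon, phantom.spec.venc)
report = fl.pixelwise_agreement(phantom.velocity, v, phantom.vessel_mask)
```

gives `slope=0.785, R^2=0.941, LoA=[-8.69, 5.51] cm/s` — at this tiny
smoke scale (16³, 4 epochs) decoded velocities already track ground
truth voxelwise; larger grids and budgets tighten the slope toward 1
(see `learnedwave.experiments` for the standard 32³ conditions).

A CLI wraps the same workflow:

```bash
learnedwave traj --mode wave --npe 4385 --cycles 8 --ef 0.75 --seed 1 -o traj.h5
learnedwave phantom --kind tubes --n-grid 48 -o data/
learnedwave demo --seed 0 --n-grid 16 -o run/
```

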