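# Methods

`learnedwave` implements joint, gradient-based optimization of a 3D
non-Cartesian phase-contrast MRI acquisition — wave-encoded (helical)
readouts with learnable phase-encode positions, per-readout helix radius
scaling and rotation — together with an unrolled model-based
reconstruction (MoDL) built from complex-valued convolutions, trained
end-to-end through a multi-coil non-uniform Fourier forward model with
analytically exact coordinate gradients. Synthetic 4-point flow-encoded
phantoms with known velocity fields provide ground truth for both
training and quantitative flow evaluation.

## Acquisition model

A readout is a helix in k-space: a constant gradient along kx with
sinusoidal ky/kz gradients. The shared base helix is parameterized by
its maximum radius `r` (grid units, i.e. cycles/FOV), cycle count `C`,
echo fraction `ef in (0.5, 1]` and readout length `NRO`. The helix
phase of sample `i` is

    t[i] = -2*pi*C * [(ef - 1/2) - (ef/NRO) * i],

monotone in `i` and zero at the echo index `NRO*(ef - 1/2)/ef`. The kx
grid coordinate is the linear map `kx = t * N / (2*pi*C)`, which spans
the partial-echo band `[-(ef - 1/2) N, +N/2]` with the echo at kx = 0.
The typography of the source expression for `t[i]` is ambiguous; this
rendering is the package's documented interpretation — it preserves the
partial-echo structure and keeps the sin/cos argument equal to the
helix phase. Each phase encode `j` then carries four per-readout
parameters:

    ky[j,i] = sr[j] * r * sin(t[i] + th[j]) + kyc[j]
    kz[j,i] = sr[j] * r * cos(t[i] + th[j]) + kzc[j]

with `sr in (0, 1]` (the radius can only shrink — hardware compliance
never redesigns the readout), rotation `th`, and centers `(kyc, kzc)`.
"No-wave" mode is the `sr -> 0` limit: straight readout lines through
the centers. Hardware limits are enforced on the discrete waveform
(`g = dk/dt / gamma_bar`, slew = `dg/dt`): each helix's transverse
component is scaled by the largest factor <= 1 that satisfies both
`|g| <= gmax` and `|slew| <= smax`, available in closed form because
both scale linearly in the transverse amplitude. Phase-encode centers
initialize from a seeded variable-density Poisson-disc draw (fully
sampled disc of radius N/32 at the center, linearly decreasing density
outward); wave and no-wave runs share one draw.

## Encoding operator and its coordinate gradients

The forward model is `y = C F S m + eps`: coil sensitivity maps times a
3D non-uniform Fourier transform of the image at the trajectory's
coordinates, plus complex Gaussian noise. The NUFFT is Kaiser-Bessel
gridding (default width 4, oversampling 1.25, Beatty shape parameter)
with the exact conjugate-transpose adjoint, so dot-product tests pass at
machine precision independent of gridding error. On full-support random
16^3 images the default operating point has ~1.6e-2 relative error
against the direct DFT; this is the intrinsic aliasing level of that
kernel choice (verified against a width-6 kernel at 3.8e-4 and a
2x-oversampled kernel at 1.5e-5), chosen for speed. A direct-summation
float64 NDFT engine provides the exact small-scale reference used by the
oracle tests.

Backpropagation of a real loss through the operator with respect to the
sampling coordinates uses Wirtinger calculus: the coordinate gradient of
the forward pass is `2 Re[conj(g_y) * J]` with `J` the spectral Jacobian
— the NUFFT of the `(-2*pi*i x_d / N)`-weighted image — i.e. three extra
NUFFT calls per backward pass; the adjoint pass is the mirror-image
expression. Differentiating the interpolation kernel instead (what a
generic autodiff engine does to a gridded NUFFT) approximates the
derivative only to gridding accuracy; both routes are implemented and
the comparison test shows the kernel route's larger deviation from the
exact-operator finite-difference gradient. Chain rule to the wave
learnables is analytic (`d ky/d th = sr r cos`, `d ky/d sr = r sin`,
unit partials to the centers), summed over readout samples per helix.

The training path runs on a small reverse-mode engine over complex
numpy arrays using the PyTorch complex-gradient convention; all
gradient routes (NUFFT coordinate Jacobians, complex convolutions,
CReLU, the data-consistency combination, checkpointing) are verified
against float64 central finite differences.

## Reconstruction

MoDL alternates a proximal-gradient data-consistency step
`z = m - 2 alpha A^H (A m - y)` with a learned complex ResNet denoiser,
for a fixed number of unrolls with shared weights, starting from
`m0 = A^H y`. The denoiser uses true complex convolutions
`(X*a - Y*b) + i(Y*a + X*b)` and CReLU activations with a global
residual connection; zero weights give the identity map. The last conv
layer initializes at zero so the untrained unroll is plain gradient
descent and cannot amplify. The reference-scale architecture (5 layers,
width 29) has 139,608 trainable parameters by the count formula
`sum_l 2 k^3 Cin Cout + 2 Cout` — the closest realizable width to the
reported 139,680 of the architecture it follows; desk-scale experiments
use much smaller widths.

`alpha` initializes at `0.5/L` with `L = ||A^H A||` estimated by power
iteration, is learnable, and is projected back into `(0, 0.8/L]` after
each optimizer step (the non-expansiveness bound of the DC step; without
the projection short runs can drift into instability). Large volumes
pass through the denoiser in overlapping blocks stitched by cutting each
overlap at its midpoint, so the cores partition the volume exactly and
the identity function survives bit for bit; uniform averaging of
overlaps was rejected because averaging k >= 3 identical IEEE754 values
is not exact, which would break the partition-of-unity contract. During
training the denoiser supports gradient checkpointing: only its input is
retained and activations are recomputed in the backward pass, bit-
compatible with the stored-activation path.

## Training

Each step: draw augmentation, simulate multi-coil k-space from the
(augmented) target volume through the current trajectory, add noise,
reconstruct, and take one Adam step (lr 1e-3, weight decay 1e-3 at full
scale) on the summed-square ratio loss `sum|m - m_hat|^2 / sum|m|^2`
(the printed form of the NRMSE loss — no square root — implemented as
printed). All cases are visited per epoch in random order with no
gradient accumulation. Augmentation: a random first-order phase
`exp(2*pi*i (a1 x + a2 y + a3 z + a4))` with `a_i` uniform in [-10, 10]
on FOV-normalized coordinates (so a coefficient is a cycle count across
the FOV) and amplitude scale in [0.3, 3]; k-space noise with a factor in
[0.5, 1.5] times the per-component noise level estimated from the median
absolute value of edge-of-k-space samples (|k| > 0.9 N/2) calibrated by
Phi^-1(0.75). After every step, `sr` is clamped into (0, 1], centers are
clamped so center + helix radius stays inside the k-space box, and
hardware limits are re-enforced. Frozen parameter groups (e.g. the
coordinates of the fixed-sampling baseline) are excluded from the
optimizer entirely, since weight decay would otherwise drag them.

The model surface is `JointSamplingModel` (cases + configuration) whose
`fit()` returns `JointSamplingResults` (learned helix set, weights,
alpha, history, `summary()`, reconstruction and persistence helpers).

## Synthetic phantoms

The quantitative phantom holds three straight tubes in a signal-giving
background block: two 3 mm tubes at 0.17 and 0.15 L/min and one 12.7 mm
tube at 1.83 L/min, parabolic (Poiseuille) profiles with
`v_peak = 2 Q / (pi R^2)`; tubes thinner than ~2 voxels fall back to
plug flow with the flow rate preserved. Brain-like training cases use
3-6 random smooth curved vessels of mixed caliber (KD-tree distance to a
fine centerline polyline). Geometry is rasterized on a 2-3x supersampled
grid and box-averaged down, so partial-volume voxels carry
volume-averaged magnitude and velocity and the flow through any
cross-section is conserved to quadrature accuracy. Velocity maps to
phase with the standard PC convention (`phase = pi v / venc`, Venc
80 cm/s default) in a 4-point referenced scheme: one reference encode
plus three orthogonal encodes. Coil maps are smooth complex lobes with
distinct phase offsets, RSS-normalized. What the generator does NOT
emulate: pulsatile waveforms (time-averaged flow only), off-resonance
and trajectory infidelity, intravoxel dephasing, anatomy. Passing tests
therefore demonstrate the pipeline's correctness and the sampling
comparison under ideal encoding, not robustness to those effects.

## Flow evaluation

Velocity decodes as `v_d = (venc/pi) angle(m_d conj(m_0))` (no
unwrapping; Venc is chosen above true speeds). The complex-difference
angiogram `sqrt(sum_d |m_d - m_0|^2)` thresholded at 10% of its maximum
gives the vessel mask. Flow rate integrates through-plane velocity times
pixel area over a cross-section (cm^3/s -> L/min). sigma_vmax is the
sample SD of per-section maximum speed over consecutive cross-sections —
a noise surrogate when the true profile is constant along the vessel.
Pixelwise agreement pools all three velocity components of all masked
voxels: OLS of one scan on the other (slope with 95% t-based CI, R^2)
plus Bland-Altman mean difference and +-1.96 SD limits. Flow-table
consistency uses the pooled CV (100 SD/mean) and ICC(3,1) — two-way
mixed effects, consistency, single measurement,
`(MS_R - MS_E)/(MS_R + (k-1) MS_E)` — the specific two-way mixed form
fixed here because consistency of repeated measurements along one vessel
is what the table encodes; an all-equal table returns ICC 1 with a
degenerate flag.

## Desk-scale study conditions

The full protocol (256^3 at 0.86 mm, 4385 phase encodes, 675-sample
readouts, 140 h of training) is far beyond a single-CPU test budget. The
experiments module freezes a scaled-down replica: 32^3 grid over a 64 mm
FOV, 68 phase encodes — the full protocol's acceleration factor 11.2 at
this matrix — 84 readout samples spanning the same 2.7 ms readout
duration, 0.75 echo fraction and ~3.5x readout oversampling ratio as the
full protocol (readout oversampling is what lets a helix acquire new
k-space positions at no scan-time cost where a straight line only
averages noise), helix radius 4 grid units with 3
cycles (hardware compliant at 9 mT/m / 150 T/m/s), 4 coils, 4 training
+ 2 validation vessel cases per seed, a 3-unroll / 3-layer / 4-feature
reconstruction, 6 epochs of single-group Adam at lr 0.01, and seeded
measurement noise at 5% of the RMS k-space signal (SNR 20, typical of
accelerated PC-MRI) added identically to every arm's simulated
acquisitions — the noise term of the encoding model, and the mechanism
(g-factor noise amplification) through which wave encoding earns its
advantage; a noiseless comparison suppresses exactly that effect.
Augmentation is disabled in this one experiment: its full-scale ranges
do not converge within a ~24-step budget in any arm, so it would reduce
the comparison to noise (the augmentation operators are tested on their
own). The three arms — learned wave, learned no-wave, fixed
Poisson-disc — share cases, initialization and seeds, and differ only in
the sampling parameterization and which parameters are learnable.

## Numerical choices and limitations

- Gradient convention: complex tensors carry `2 dL/d(conj z)`
  (PyTorch's), real leaves the plain derivative; FD tests pin every op.
- FD oracles run the exact NDFT engine in float64 with central
  differences, step 1e-4 grid units (1e-5 through full unrolls, where
  curvature dominates the truncation error).
- Degenerate inputs: all-zero loss reference, empty k-space edge shell,
  empty cross-sections, overlapping tubes and out-of-range `sr` raise;
  reconstruction divergence (norm explosion) raises rather than
  returning garbage.
- The no-wave equivalence (`sr -> 0`), rotation periodicity and the
  circle identity hold to machine precision by construction.
- Limitations: no off-resonance/B0 or T2* modeling along the readout, no
  trajectory-measurement correction, no pulsatile flow, no 5-point
  balanced encoding (4-point referenced only), no conjugate-gradient DC
  variant, and the desk-scale comparison's margins are those of a
  minutes-long training budget, not a converged model.
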