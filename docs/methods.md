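# Methods

`wavetof` simulates and reconstructs wave-encoded 3D time-of-flight (TOF)
MR angiography. This note records the model, the conventions and
numerical choices the implementation commits to, what the synthetic data
generator does and does not emulate, and the known limitations.

## Signal model

During each readout, sinusoidal gradients play on the phase (y) and
partition (z) axes with a π/2 phase offset:

    gy(t) = G_max sin(2π f t),   gz(t) = G_max cos(2π f t),
    f = N_cyc / T_read,          T_read = 1 / bw_per_pixel.

Integrating them yields sinusoidal k-space deflections riding on the
linear readout — a corkscrew trajectory. In hybrid (kx, y, z) space the
effect of the waves is a unit-modulus point-spread-function (PSF)
modulation, and an accelerated acquisition of image s is

    k = M · F_z · F_y · PSF(kx, y, z) · F_x · C · s,

with C the coil sensitivities, F the Fourier transforms per axis,
PSF = exp(−i·2π·(ky_wave(kx)·y + kz_wave(kx)·z)), and M the ky–kz
sampling mask. Wave-CAIPI solves the least-squares problem for this
operator on a staggered 2D-CAIPI lattice; CS-wave adds L1 penalties in
the finite-difference-gradient and Haar-wavelet domains on a
variable-density Poisson-disc pattern. Removing the PSF gives the plain
2D-CAIPI / CS baselines on the same code path.

### Conventions

- FFTs are centered (DC at index ⌊N/2⌋) and orthonormal on every axis,
  so the adjoint equals the inverse at full sampling and dense-matrix
  oracles compare directly. Voxel centers sit at (i − ⌊N/2⌋)·Δ.
- Phase sign: PSF and flow phase use φ = +2πγ(moment·coordinate) with
  the negative sign inside the complex exponential of the forward
  model; a single global convention shared by the trajectory, PSF and
  phantom modules.
- The image lives on the readout-oversampled x grid during encoding
  (zero-padded symmetrically); the reconstruction returns the centered
  nominal FOV.
- Wave deflections are stored with their temporal mean removed. A
  constant k-offset contributes only a y- (or z-) dependent static
  phase, never a displacement, and demeaning keeps |ky_wave| equal to
  the integrated-sine amplitude γG_max/(2πf).
- Units: gradient amplitudes mT/m, times ms, bandwidth Hz/pixel,
  velocities mm/s, trajectories cycles/m; conversions to SI happen
  inside the functions that need them. γ = 42.577478518 MHz/T.

## PSF spread and readout oversampling

A voxel at (y, z) is displaced along the readout by
Δx(t) = (gy(t)·y + gz(t)·z)/G_read, where G_read is the readout
gradient implied by the pixel bandwidth. The reported **spread-out
range** is the maximum one-sided |Δx| over the FOV-corner voxels,
evaluated on the sampled trajectory; it is bounded by
(G_max/G_read)(|y| + |z|). Whether the reporting convention for this
quantity is one-sided or axis-summed is not fully determined by the
protocol description; the one-sided-measured convention implemented
here reproduces the protocol's reported ≈296 mm for the scanner setup
(10 mT/m, 15 cycles, 121 Hz/px, 256 samples, 200×200 mm FOV, 26.4 mm
slab) within the stated 10 % band, and the axis-summed bound also
falls inside that band.

Oversampling rule: displaced signal must stay inside the oversampled
readout FOV, |x| + spread ≤ os·FOV_x/2. At the scanner matrix (256
samples) the protocol's 10 mT/m respects this with os = 6. On coarse
desk-scale grids the readout gradient shrinks proportionally, so
`desk_wave_params` caps the amplitude at the largest wrap-free value
(4.01 mT/m at a 64-sample readout) rather than letting the discrete
model wrap voxel spread circularly.

## Flow ghosting

Spins moving with velocity v acquire φ(t) = 2πγ(m1_y(t)v_y +
m1_z(t)v_z) from the first gradient moment m1 = ∫G·t dt, which
oscillates at the wave frequency with a linearly growing envelope. The
modulation is periodic over the readout with N_cyc cycles, so vessel
signal replicates at multiples of N_cyc pixels along the frequency
encoding direction. The ghost-to-signal ratio metric averages the
reconstruction magnitude over exactly those shifted copies of the
vessel mask (excluding a 2-voxel dilation of the vessels) and divides
by the mean vessel magnitude. Few large cycles (25 mT/m, 6 cycles)
produce a ~6× larger first moment than the protocol's many small
cycles (10 mT/m, 15 cycles); the simulations reproduce both the
ordering and monotone growth with flow speed. Second- and higher-order
moments and pulsatility are neglected.

## Trajectory calibration

Projection scans with and without the wave gradients at slice offsets
r give phase differences −2πk_wave(t)·r. Two estimators are provided:
a single-reference-offset division and (default) a least-squares slope
fit of the temporally unwrapped phase across several offsets, which is
more robust to noise. Offsets must satisfy |r| < 1/(2·max|Δk| per
sample) or the temporal unwrapping is ambiguous; the defaults (±20,
±40 mm) respect this for all readouts used here. Gradient
imperfections are modelled as a per-axis timing delay plus subtractive
decaying-exponential eddy-current kernels.

## Sampling patterns

- 2D-CAIPI: sample iff ky ≡ 0 (mod R_y) and kz ≡ (ky/R_y)·shift
  (mod R_z). Defaults R=4→(2,2,1), R=6→(2,3,1), R=8→(2,4,1), the
  lowest-mean-g-factor choices for these totals. The lattice is
  periodic with period R_y·R_z in ky and R_z in kz.
- Poisson disc: dart throwing in randomized order with exclusion
  radius r(k) = r0(1 + 2·|k|/|k|max) in index units; r0 is bisected
  until the achieved acceleration is within 5 % of target.
  Deterministic per seed. A fully sampled central calibration block is
  optional and off by default (sensitivities come from a separate
  low-resolution scan, as in the acquisition being modelled).
- For multi-R comparisons the Poisson masks are **nested** (the R=8
  samples are a subset of R=6, which is a subset of R=4), so quality
  trends across R measure undersampling, not mask-realization luck.

## Reconstruction

- Least squares: LSQR-family Krylov iterations; the tolerance (default
  1e-3) applies to the relative residual ‖As−k‖/‖k‖ — on noiseless
  consistent data the solver converges to that accuracy, on noisy data
  the iteration cap (default 200) terminates it, matching the
  reference reconstruction practice this models.
- CS: Fletcher–Reeves nonlinear conjugate gradient with restart every
  50 iterations, smoothed modulus |u| ≈ √(|u|²+ε), ε = 1e-15, and a
  backtracking Armijo line search (sufficient-decrease 0.01, shrink
  0.6). Because the data term is an exact quadratic along the search
  direction and the penalty inputs are linear, one operator application
  per iteration suffices and the line search is transform-free. The
  step is initialized at the exact data-term minimizer. Defaults:
  γ_G = γ_W = 3e-4, tolerance 3e-3 on the relative gradient norm, 100
  iterations, 3-level periodized Haar (orthonormal), anisotropic
  forward differences with zero boundary, Wirtinger-convention
  gradients, deterministic zero-filled initialization.
- Iterative solves in the experiment driver run in single precision;
  the quality metrics operate far above float32 resolution. Oracle
  tests use double precision throughout.

## Quality metrics

- g-factor: pseudo-replica Monte Carlo. Pure-noise k-space replicas
  (iid complex Gaussian, identity coil covariance) pass through the
  accelerated and fully sampled pipelines; g = SD_accel/(SD_full·√R)
  per voxel, with SDs across replicas of the complex reconstruction.
  g_mean/g_max are evaluated over the object support (the region of
  interest is otherwise unspecified in the protocol being modelled).
- CBR = (mean_vessel − mean_background)/SD_background on magnitude
  source volumes; the background is the support minus a 2-voxel
  dilation of the vessel mask.
- SSIM: Gaussian window σ = 1.5, K1 = 0.01, K2 = 0.03, population
  covariance, averaged over the filter-valid interior (matching the
  standard scalar implementation). Vessel-masked SSIM averages the
  same local map over vessel pixels only, so a full mask reproduces
  the standard value exactly.
- Vessel mask: threshold at mean + 2·SD of the reference MIP, then
  remove connected components below 5 pixels. Scale-invariant and
  deterministic.

## Synthetic data

The phantom emulates a 3D TOF slab at desk scale — default 64×64×16
voxels over 200×200×26.4 mm, 8 coils:

- Vessels: persistent-random-walk centerlines, radii drawn from
  2–5 mm tapering to 40 % distally, rasterized with a one-voxel soft
  edge so sub-voxel distal segments carry partial-volume intensity.
  Each branch carries a constant axial velocity drawn from
  100–400 mm/s (bracketing cerebral arterial speeds).
- Background: ellipsoidal "head" of mean intensity 0.3 (vessels 1.0)
  with 40 % smooth multiplicative texture, emulating imperfectly
  saturated static tissue; this puts the reference
  contrast-to-background ratio in the low-to-mid single digits, the
  regime of real TOF source images. Complex Gaussian noise of SD 0.01 per k-space
  sample.
- Coils: Gaussian lobes on a ring around the FOV with smooth phases,
  RSS-normalized to 1 on the support and zero outside. The
  low-resolution calibration estimator (Hann-apodized central k-space
  block divided by its RSS) recovers the truth maps to <5 % in the
  support interior; the 1–2 voxel boundary shell is excluded because
  windowed low-resolution estimation cannot follow the support
  discontinuity. Full subspace (ESPIRiT-style) calibration is out of
  scope; truth maps are always available in simulation.
- TOF inflow physics (TONE ramp, saturation recovery) is emulated by
  the static vessel/background contrast, not Bloch-simulated; B0/B1
  inhomogeneity, motion, pulsatility and realistic vascular anatomy
  are not modelled. Passing tests therefore demonstrate correctness of
  the encoding/reconstruction/analysis chain under idealized contrast,
  not in-vivo image quality.

## Problem sizes

Experiments and tests run at deliberately small matrices chosen as desk
analogues of the scanner protocol: 64×64×16 (8 coils) for the method
comparison and flow studies, 32×32×16 for g-factor Monte Carlo (30–100
replicas; 500 for the two-coil analytic check), and ≤8×8×4 grids for
brute-force NUDFT and dense-matrix oracles. The scanner-scale
256×256×44 / 32-coil geometry is a parameter choice away but not
exercised by default.

## Behaviour of the method comparison at desk scale

The retrospective comparison reproduces the headline behaviour of
wave encoding: 2D-CAIPI collapses at R = 8 (noise amplification in both
CBR and SSIM) while wave-CAIPI degrades only gently; CS-wave
outperforms plain CS on vessel-masked SSIM; and wave-CAIPI has the
highest standard SSIM throughout. Two fine-grained comparisons are
genuinely tied in this regime and the corresponding strict assertions
are expected to fail: the CBR of CS-wave edges out wave-CAIPI by ~1–2 %
because L1 denoising lowers the background SD below the least-squares
noise floor — a synthetic background compressible enough to simulate
cheaply is also compressible enough for CS to denoise perfectly,
unlike real anatomy; and the per-method SSIM-vs-R trend of the
fixed-100-iteration CS solver can show ~0.005-level inversions, since
the truncated solver's implicit early-stopping regularization
interacts non-monotonically with the sample count.

## Known limitations

- The CS regularization weights are the protocol values interpreted on
  this phantom's unit intensity scale; the reference reconstruction's
  data were in arbitrary scanner units, so the effective regularization
  strength is not identical.
- The Poisson-disc density law (linear radius growth, α = 2) is one
  reasonable realization of "variable density"; the modelled
  acquisition did not publish its law.
- The pseudo-replica g-factor assumes identity coil noise covariance.
- `estimate_trajectory` requires calibration offsets compatible with
  temporal phase unwrapping (documented bound); no spatial-unwrapping
  fallback is provided.
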