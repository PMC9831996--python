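# Methods

`octforce` implements an image-based tool–tissue force-estimation pipeline
for optical coherence tomography (OCT): shear-wave elastography supplies a
per-location stiffness proxy (the phase velocity), volumetric or
surface-map image data supply the deformation, and a Siamese DenseNet
regressor maps both to the axial contact force. Because the original OCT
recordings are not publicly deposited, the package ships a physics-inspired
simulator so every stage is buildable and testable end to end.

## Synthetic data model

**Materials.** Gelatin phantoms are parameterised by weight ratio
`c ∈ {5, 7.5, 10, 12.5, 15, 17.5, 20} %`. Young's modulus comes from a
piecewise-linear map anchored at the two calibrated points
(5 % → 17.42 kPa, 15 % → 56.04 kPa) and extrapolated linearly to 20 %.
Shear-wave speed uses the incompressible soft-tissue approximation
`c_s = sqrt(E / 3ρ)` with ρ = 1000 kg m⁻³ (Poisson ratio 0.5). The
`tissue_like` class draws a per-sample modulus from a lognormal centred on
18 kPa (soft muscle range, ~20 % spread) and renders a roughened surface
with stronger speckle contrast; it stands in for ex-vivo soft tissue in the
transfer experiment. In the study generator each *phantom* of a gel
additionally receives a lognormal modulus jitter (σ = 0.06), reflecting
batch-to-batch variability of gelatin preparation; without it the phase
velocity degenerates into a categorical label with exactly one support
point per gel, which no measurement campaign exhibits.

**Shear-wave sequences.** A continuous 1 kHz surface excitation produces,
below the sample surface, an OCT phase field
`φ(x, t) = A·exp(−x/L)·sin(2πf (t − x/c_s))` with lateral position `x`,
damping length `L` (3 mm default) and source amplitude `A = 0.5 rad`.
Magnitude carries static speckle (smoothed exponential intensities) with a
bright specular surface line; complex Gaussian noise is added at a
configurable SNR (20 dB default). The default geometry matches a
swept-source scanner: 476 × 32 px over 3.5 × 3 mm at 14.2 kHz; tests and
the desk study reduce the depth to 48 px (identical pitch) and the
excitation duration to 0.1–0.2 s, since the estimator only uses 32 rows
beneath the surface and 800-sample subsets.

**Palpation records.** A spherical-tip tool indents the surface with a
Gaussian-bowl profile (σ = 0.75 mm); the sub-surface speckle texture
translates axially with the surface. Contact force follows a Hertzian
sphere, `F = (4/3)·E/(1−ν²)·√R·δ^{3/2}` with ν = 0.5 and tool radius
R = 1 mm, sampled on a 500 Hz force clock whose origin is jittered
relative to the volume clock so force labels always require genuine
interpolation. Training trajectories are three raised-cosine indentation
cycles to 2.5 mm with per-cycle peak velocities in 0.5–3 mm s⁻¹;
evaluation trajectories step to 20 random depths in 0.5–2.5 mm at
2–7 mm s⁻¹. Everything is a pure function of (specification, seed).

What the simulator does *not* model: interferometric optics, refraction,
viscoelasticity and wave dispersion, wave reflections at boundaries, motion
artefacts, and nonlinear tissue mechanics. Passing tests therefore
demonstrate correctness of the *pipeline* under first-order physics, not
performance on real OCT recordings.

## Phase-velocity estimation

The estimator crops 32 px beneath the (per-column, maximum-intensity)
surface, unwraps the complex phase along time at each pixel, averages over
depth, and draws 30 random 800-sample temporal subsets (uniform starts,
with replacement, seeded). Each subset is Fourier-transformed over
(time, lateral) with zero-padding (4096 × 256 by default); the
forward-travelling quadrant is extracted via the real-input rFFT symmetry.
Three filters apply in order: high-pass (100 Hz default; the spectrum near
0 Hz carries bulk motion), an admissible-velocity sector (0.5–15 m s⁻¹),
and a threshold at 10 % of the running spectral maximum. The phase
velocity of a subset is `v = f_i / k_j` at the maximum-amplitude bin
(wavenumber in cycles per metre, so no 2π factor; ties broken toward the
lowest frequency then lowest wavenumber), and the reported velocity is the
mean over subsets.

Numerical notes: zero-magnitude samples (undefined angle) are filled by
linear interpolation of the in-phase/quadrature components along time
before unwrapping. The lateral aperture (32 px over 3 mm) quantises the
wavenumber axis; padding to 256 gives Δk = 41.7 m⁻¹, which is adequate for
recovery-within-tolerance checks but ties neighbouring gels' velocities.
Contexts that need all seven gels separated (the monotonicity check and
the study's per-location velocities) pad the lateral axis to 1024. The
velocity tolerance used in tests is the padded-bin bound
`Δv = c · max(Δf/f₀, Δk/k₀)`.

## Pre-processing

Volumes are cropped to 200 px along depth and resampled tri-linearly to a
cube (32³ full scale, 16³ desk), normalised per volume to [0, 1] (the
reference uses its own statistics). The 2D representation extracts a
surface height map as the argmax-depth of each lateral column, masks
entries whose column maximum is below 50 % of the volume mean, and closes
holes by Delaunay-based linear interpolation with nearest-neighbour
fallback outside the convex hull (exact on planes, no overshoot). Depth,
not projected intensity, is stored; the map is passed to models scaled by
the crop length. Force labels are linear interpolations of the force
stream at each volume timestamp; extrapolation is an error.

## Model

Both representations share one architecture family: a three-layer
convolutional stem (shared weights) processes the input and the zero-force
reference; the Siamese stage runs as one stacked batch so that batch-norm
statistics are computed over the branch mixture — the same statistics the
running-average normalisation uses at evaluation. (Normalising each branch
separately during training makes train- and eval-mode networks different
functions; with near-constant reference maps this produced catastrophic
eval bias.) The stem outputs are concatenated channel-wise and processed
by densely connected blocks (BN → ReLU → 3^d conv, growth rate 6 for 3D /
8 for 2D; each layer sees all previous feature maps) with compression-0.5
transitions (1×1 conv + stride-2 average pooling, skipped once maps reach
one voxel). Global average pooling yields the feature vector; with SWEI
fusion the z-scored phase velocity is appended; two fully connected layers
(He-initialised, BN on the hidden layer) produce one scalar. Full-scale 2D
and 3D configurations land within 25 % of each other in parameter count
(59.2 k vs 66.9 k), with the 2D model using one extra block, growth 8 and
a wider stem.

The layers are implemented in numpy (channels-last) with hand-written
backward passes; convolutions dispatch between an im2col GEMM, a
shift-and-GEMM formulation (cheaper when output channels are few), and a
transposed-convolution input-gradient path. All gradients are validated by
directional finite differences in the test suite.

## Training and experiments

MSE loss on z-scored force labels; Adam (default moments); one-cycle
cosine learning-rate schedule. Full-scale defaults are 150 epochs at
batch 128 with lr 1e-4→1e-3. The desk profile — the
configuration every test and the acceptance script run — uses 16³ volumes
(16×16 maps), 7 gelatin concentrations × 2 phantoms × 3 locations, one
sinusoidal and one random-step record per location with 8 volumes each,
20 epochs at batch 32, and lr_max 3e-3 (the compact desk models see ~200
optimisation steps, an order of magnitude fewer than the full-scale
schedule; the higher peak rate was chosen on single-material convergence
probes). Per-gel transfer-matrix models train for 60 epochs because their
training sets are a single phantom (~24 samples = 1 step per epoch).
Best-epoch selection is by validation rMSE; no augmentation.

Training uses sinusoidal-trajectory records only; validation and test use
random-step records only (enforced programmatically). Leave-one-stiffness-
out folds hold out all phantoms of one gel, splitting them into validation
(first third of phantoms) and test (rest). The tissue-transfer experiment
evaluates the mean-voting ensemble of the seven fold models per variant on
tissue-like records never used in training.

Desk-scale problem sizes were chosen so the complete three-seed study
(generalisation + transfer matrix + tissue transfer) runs in roughly
15 minutes on one CPU; they are stated here as the package's reference
configuration.

## Known limitations

- Desk-scale 3D models underfit relative to their 2D counterparts (the
  surface map is a far easier input at 16³ resolution); on tissue-like
  data their predictions track force shape less tightly (Pearson r ≈ 0.85
  vs ≈ 0.98 for 2D), a larger spread than full-scale training exhibits.
- The concentration→modulus map is linear through two calibration points;
  real gelatin curves are mildly nonlinear.
- Velocity quantisation from the 3 mm lateral aperture is the dominant
  SWEI error source; multi-frequency dispersion analysis is out of scope.
- The simulator's tissue class changes texture statistics at evaluation
  time (domain shift) but cannot emulate anisotropy or vascularisation.
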