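# Methods

## Polarimetric model

A voxel's measurement is a round-trip Jones matrix J; a homogeneous
birefringent slab acts as an elliptical retarder
J = cos(δ/2)·I + i·sin(δ/2)·(A·Σ), where A is the unit Poincaré axis and
δ = 4πΔn·Δz/λ₀ the round-trip retardation across depth Δz. The Stokes
convention is q = |e₁|² − |e₂|², u = 2Re(e₁e₂*), v = −2Im(e₁e₂*), with
Σ = (σ_z, σ_x, σ_y) matched to it so that the e^{+iδ/2} eigenvector maps
onto +A exactly. The Jones→Mueller map is M = A(J⊗J*)A⁻¹ in the
(I, Q, U, V) basis; the basis-change matrix is written out in
`sclerheo.jones`.

Retardance is extracted by the Lu–Chipman polar decomposition
M = M_Δ·M_R·M_D: the diattenuator is built from the first row of M, the
depolarizer magnitude from the symmetric part of what remains, and
R = arccos(tr(M_R)/2 − 1), with the arccos argument clipped to [−1, 1] for
numerical safety. Degenerate pixels (diattenuation ≥ 1, singular factors —
e.g. from a singular cumulative matrix) are flagged invalid rather than
raising inside the vectorized pipeline; the scalar API raises.

The estimator wraps at R = π: a single-separation measurement cannot
distinguish R from 2π − R. The phantom generator refuses parameter
combinations whose retardance over the guarded separation reaches π, and
the pipeline flags pixels within `wrap_margin` (default 2 %) of π.

## Processing chain and defaults

- **Averaging**: complex moving average per B-scan, kernel (3, 3) pixels,
  centred, truncated at edges. Before averaging, each neighbour is
  multiplied by the unit phasor of the Frobenius inner product with the
  window centre — the least-squares optimal global-phase alignment. Raw
  complex averaging across speckle phase would cancel the signal; aligning
  on a single matrix element is fragile when the dominant element differs
  between neighbours, so the inner-product rule is used. The metadata
  noise floor is divided by the kernel area; edge pixels, averaged over
  truncated windows, carry slightly less noise reduction than the metadata
  implies (a conservative bias in the SNR screen's direction at the top
  edge is the only visible consequence: the half-pixel depth shift of
  truncated axial windows perturbs the two boundary rows of the Δn map by
  Δz/(2·separation), ~0.4 % of the volume mean at separation 8).
- **Local matrices**: J(z+s)·J(z)⁻¹ at s = 8 pixels (49 μm at the
  6.125 μm axial pitch). Singular J(z) flags the pixel, it does not raise.
- **Effective SNR**: 10·log₁₀(Σ|J_ij|²/Σσ²_ij), the four-channel intensity
  sum against the summed per-channel noise floor, computed on the averaged
  volume; the map on the local grid takes the minimum of the two depths
  entering each local matrix (conservative for both screening and bias
  correction). Threshold 10 dB.
- **Birefringence**: Δn = Rλ₀/(4πΔz), λ₀ = 1.31 μm.
- **Bias correction**: retardance estimates are non-negative, so noise
  biases them upward, most strongly near R = 0 and at low SNR. A table of
  E[R̂ | R, SNR] is built by Monte-Carlo simulation of the *production*
  estimator — two unitary matrices at the given SNR under additive
  circular complex Gaussian noise, local matrix, Lu–Chipman — on a
  21-point retardance grid × 5–40 dB in 5 dB steps, 2000 draws per node,
  deterministic given its seed. Per-pixel correction inverts the table at
  the pixel's SNR: monotone cubic (PCHIP) interpolation in retardance per
  SNR slice, linear blending between slices, nearest-edge extrapolation in
  SNR. Measured values below the SNR-specific zero-retardance bias floor
  map to 0 (the only consistent inverse, since bias makes 0 unreachable);
  values above the table maximum clamp to π. Correcting individual pixels
  with the inverse of a *mean* map is exact only in expectation; the
  residual Jensen error is far below the few-percent accuracy targeted
  here.
- **DOAU**: each local matrix is diagonalized; the eigenvector whose
  eigenvalue leads its partner in phase (arg(λᵢ/λⱼ) ∈ (0, π), the fast
  axis, invariant to global phase) is mapped to its Stokes axis; the
  (q, u, v) components are averaged over a centred (5, 21)-pixel kernel
  per B-scan (≈ 31 × 129 μm² at the default pitches) and the norm taken.
  Uniform axes give 1; N i.i.d. random axes give E[DOAU²] = 1/N. The
  deterministic fast-axis choice (rather than folding each axis to a
  canonical hemisphere) is essential for that null: folding would place
  all representatives on a half-sphere and bias the resultant length to
  ~0.5 for random axes, and would also score a mixture of orthogonal-axis
  domains as perfectly uniform — the opposite of what the screen is for.
  The general eigenvector→Stokes helper still offers hemisphere
  disambiguation (two orthogonal eigenpolarizations of one retarder are
  Poincaré antipodes and fold to one representative), which is the right
  tool when the fast/slow distinction itself is not wanted. Threshold 0.9.
- **Volume mean**: arithmetic mean of Δn over pixels passing validity,
  SNR and DOAU screens (the screens commute); the survivor count is
  reported, and an empty mask raises with per-filter counts.

## Mechanics

Strain is (L − L₀)/L₀ with L₀ the 5 mm pre-stressed gauge length; stress
is force over the initial cross-section (engineering stress). The final
loading ramp is the maximal non-decreasing displacement suffix of the
record, with any leading hold plateau trimmed.

The exponential model σ = a(e^{bε} − 1) is fitted on 0–6.5 % strain by
bounded least squares. The solver works in (E₀, b) = (a·b, b), which is
smooth in the b → 0 limit (linear data recover the product a·b = k while
b alone is unidentifiable). Initialization is deterministic: b₀ from the
log-slope of a smoothed finite-difference derivative, a₀ from matching the
endpoint. The 0.04 N pre-load defines the zero-strain reference state and
its stress level is the fit's datum: the model describes the pseudo-elastic
stress developed *above* the pre-stressed state, so the stress at the
smallest in-range strain is subtracted before fitting (configurable:
`datum="none"` or an explicit value). Leaving the pre-load inside the
fitted stress would force the model to absorb a constant offset it cannot
represent and biases b by roughly −20 % at typical geometry — the datum
choice is what makes the fitted parameters agree with the generating ones.

Derived parameters are exact identities of the model: E₀ = a·b,
E(ε) = a·b·e^{bε} = b(σ + a), structural stiffness = E₀ × thickness.

Preconditioning (ten cycles to 6.5 %) is represented in the generator's
displacement profile but not modelled viscoelastically; after
conditioning, the tissue response is treated as pseudo-elastic, which is
why only the final ramp is analyzed and the fit window matches the
conditioning range.

## Morphometry

Segmentations are assumed to be in physical (geometric) millimetres; any
optical-path correction happens upstream. Polygon areas use the exact
shoelace value (via `shapely`, which also rejects self-intersections);
mask areas are pixel count × pixel area. Thickness = area / width.

## Statistics

Pearson's r with the exact two-sided t test (n − 2 df), stars strictly
below 0.05/0.01/0.001, OLS lines for plotting. No multiple-testing
correction by default — the region × parameter grid is reported cell by
cell — with Holm adjustment available (`holm=True`) for users who want
family-wise control. Eye-level clustering across regions is not modelled;
each region is analyzed as an independent one-row-per-eye sample, a known
limitation.

## Synthetic data

The phantom generator composes per-voxel retarder increments into
cumulative round-trip matrices, multiplies each A-scan by a random unit
phasor (speckle-phase surrogate) and adds circular complex Gaussian noise
per element, with the per-channel variance set so the four-channel
effective SNR equals the requested value (σ² = ½·10^(−SNR/10) against the
unit-determinant signal's total power of 2). It does *not* simulate full
coherent speckle, depth-dependent attenuation, or axis variation within a
voxel; passing recovery tests therefore demonstrates correctness of the
estimator chain under the stated noise model, not robustness to every
property of real tissue data. Axis fields: uniform, two-domain (lateral
split), von-Mises–Fisher dispersed (κ → 0 is uniform on the sphere), or
i.i.d. random.

Tensile records follow the protocol constants: 0.04 N pre-load, ten
0–6.5 % preconditioning cycles and a final 0–18 % ramp at 1.8 mm/min on a
5 mm gauge, sampled at 10 Hz (a typical tester logging rate; the ramp
alone is 30 s ≈ 180 fit samples), with multiplicative Gaussian force
noise (default 1 %).

Cohorts draw a latent organization variable L per sample-region and build
unit-variance scores z = (L + s·e)/√(1+s²) for birefringence and for the
tangent modulus, with s calibrated analytically so that the *population*
correlation between Δn and structural stiffness (including the independent
thickness noise) equals the designed target:
corr = [1/(1+s²)]/√(1 + (c_t/c_E)² + c_t²). Targets above the feasibility
bound (thickness noise alone caps the correlation) raise with the bound.
The exponential power b decreases with L, mirroring the expectation that
less organized tissue stiffens faster under extension. Default scales —
Δn: 1.5×10⁻³ ± 12 %, E₀: 0.8 MPa ± 25 %, thickness: 0.8 mm ± 8 %, b:
40 ± 10 %, 19 samples per region at 30 dB — are chosen as realistic
magnitudes for porcine sclera and held fixed; small coefficients of
variation keep the linearized calibration accurate on the raw scale.
Every generator is bit-reproducible given its seed.

## Problem sizes

Tests and the acceptance script use phantoms of 64×64×4 voxels for
recovery studies (≈ 14 000 screened pixels per volume) and 40×24×2 voxel
volumes inside the 100-seed cohort studies; these sizes give
measurement-error standard deviations an order of magnitude below the
cohort spreads being estimated, so the cohort-level sampling distribution
of r, not pipeline noise, dominates the results. The acceptance script
runs the cohort study at 30 seeds; the test suite runs 100.

## Known limitations

- Single-scattering, nondepolarizing model; no attenuation, no
  bulk-motion or phase-drift artifacts, no depth-dependent axis within a
  layer except where explicitly constructed.
- The bias table assumes equal SNR at the two depths of a local pair (the
  pipeline feeds it the minimum of the two).
- Truncated-window edge effects perturb the two axial boundary rows of
  each Δn map (~0.4 % of the volume mean at the defaults).
- Viscoelasticity is not modelled; the exponential fit presumes a
  conditioned, pseudo-elastic response.
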