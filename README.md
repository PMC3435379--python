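# sclerheo

Scleral birefringence from Jones-matrix PS-OCT, uniaxial elastic
parameters from tensile testing, and the correlation between the two.

The stiffness of the sclera — the collagenous outer shell of the eye — is
implicated in myopia and glaucoma, and collagen fiber organization is
thought to drive it. Polarization-sensitive optical coherence tomography
(PS-OCT) measures tissue birefringence Δn, an optical proxy for fiber
organization, non-destructively. `sclerheo` implements the full analysis
chain needed to test the birefringence–stiffness link on scleral strips:

1. **Birefringence imaging** (`sclerheo.birefringence`, `sclerheo.jones`).
   Per-voxel 2×2 complex Jones matrices are phase-aligned and moving-averaged,
   local round-trip matrices are formed at an 8-pixel (49 μm) depth
   separation, J(z+Δz)·J(z)⁻¹, and their retardance R is extracted by the
   Lu–Chipman polar decomposition of the corresponding Mueller matrix.
   Birefringence follows as Δn = Rλ₀/(4πΔz) (λ₀ = 1.31 μm). A Monte-Carlo
   bias table, built by simulating the production estimator under additive
   complex Gaussian noise, removes the noise-floor bias of the retardance
   estimate as a function of effective SNR. Pixels are screened by
   effective SNR (> 10 dB) and by the degree of optic axis uniformity
   (DOAU > 0.9) — the norm of the kernel-averaged Stokes axis of the local
   eigenpolarizations (1 = uniform axes, ~1/√N = random) — before the
   volume mean is taken.
2. **Morphometry** (`sclerheo.morphometry`). Cross-sectional area from a
   segmented boundary polygon (or mask) and laterally-averaged thickness
   = area / strip width.
3. **Mechanics** (`sclerheo.mechanics`). Engineering stress–strain from a
   tensile record, fitted with the exponential soft-tissue model
   σ = a(e^{bε} − 1) on 0–6.5 % strain. Extracted parameters: tangent
   modulus at 0 % strain E₀ = a·b, structural stiffness E₀ × thickness,
   and the power b (the slope of tangent modulus against stress, since
   E = b(σ + a)).
4. **Cohort statistics** (`sclerheo.stats`). Two-sided Pearson tests of
   birefringence against each elastic parameter per scleral region (A–D,
   1–17 mm from the optic nerve head), with significance stars at
   p < 0.05 / 0.01 / 0.001 and OLS regression lines.
5. **Synthetic ground truth** (`sclerheo.synthetic`). Forward-modelled
   Jones phantoms (layered retarders, speckle phase, detection noise at a
   set SNR), protocol-faithful tensile records (0.04 N pre-load, ten
   preconditioning cycles to 6.5 % at 1.8 mm/min, ramp to 18 %), and
   cohorts in which a latent fiber-organization variable drives both Δn
   and stiffness with a designed Pearson correlation.

## Worked example

```python
import numpy as np
from sclerheo import birefringence as bf, synthetic as syn
from sclerheo import mechanics as mech, stats as st

# phantom with known dn = 1.5e-3 at 30 dB SNR, full pipeline
spec = syn.PhantomSpec(dims=(64, 64, 4), birefringence=1.5e-3, snr_db=30.0, rng_seed=0)
vol = syn.simulate_jones_volume(spec)
table = bf.build_bias_table(rng_seed=0)
res = bf.process_volume(vol, bf.PipelineConfig(rng_seed=0), bias_table=table)
print(f"mean birefringence: {res['mean_birefringence']:.4e}  (n_valid = {res['n_valid']})")

# tensile record from a = 0.02 MPa, b = 40 with 1% force noise
rec = syn.simulate_stress_strain(0.02, 40.0, area_mm2=3.2, noise_frac=0.01, rng_seed=0)
strain, stress = mech.compute_stress_strain(rec)
p = mech.fit_exponential(strain, stress).with_thickness(0.8)
print(f"a = {p.a:.4f} MPa, b = {p.b:.2f}, E0 = {p.tangent_modulus_0:.4f} MPa")

# a 19-eye cohort with designed region-B correlation, Pearson table
samples, truth = syn.simulate_cohort(syn.CohortSpec(rng_seed=0))
tbl = st.build_results_table(truth)
print(tbl[tbl.parameter == "structural_stiffness"][["region", "r", "p", "stars"]])
```

prints

```
mean birefringence: 1.4972e-03  (n_valid = 14336)
a = 0.0204 MPa, b = 39.67, E0 = 0.8086 MPa
region         r            p stars
     A  0.248325 3.053107e-01
     B  0.883685 5.288142e-07   ***
     C  0.192922 4.287604e-01
     D -0.029364 9.050135e-01
```

The recovered volume mean (1.497×10⁻³) sits within 0.2 % of the planted
birefringence; the fitted (a, b) recover the generator's values within the
force-noise level; and the cohort table stars the region whose designed
correlation is strong (B) while leaving the near-null regions unstarred.

A command-line interface mirrors the library:

```sh
sclerheo simulate phantom --out out/         # synthetic Jones volume (HDF5)
sclerheo biref --input out/phantom.h5 --out out/   # maps + summary JSON
sclerheo mech --input record.csv --meta record.json
sclerheo correlate --cohort cohort.csv --out table.csv
sclerheo run --config demo.yaml --out out/   # full pipeline + manifest
```

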