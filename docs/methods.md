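# Methods

This note documents the models, numerical choices and known limitations of
`dktihist`, in the spirit of the methods documentation of mature scientific
packages. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Diffusion kurtosis signal representation

The signal model is the standard cumulant expansion of the diffusion MRI
signal to second order in b:

    ln S(b, n) = ln S0 − b D_app(n) + (b²/6) MD² W_app(n),

with D_app(n) = nᵢnⱼDᵢⱼ, W_app(n) = nᵢnⱼnₖnₗWᵢⱼₖₗ, MD = tr(D)/3 and
K_app(n) = (MD²/D_app(n)²) W_app(n). D is a symmetric rank-2 tensor
(mm²/s, 6 unique elements); W is a fully symmetric rank-4 tensor
(dimensionless, 15 unique elements). Unique-element bookkeeping carries
the permutation multiplicities (1/2 for D; 1/4/6/12 for W), so projections
are 6- and 15-term dot products.

**Estimator.** Ordinary (unweighted) linear least squares on log-signals
with 22 unknowns: ln S0, the elements of D, and the elements of X = MD²W;
W is recovered as X/MD² using the fitted MD. The model is exactly
log-linear, so the noiseless round trip is limited only by the
conditioning of the design matrix (observed ~1e-12 relative error on the
emulated protocol). Weighted or constrained variants (e.g. positivity of
directional kurtosis) are deliberately not the default: the reference
estimator's constraint settings for this analysis are not documented, so
the unconstrained fit is the reproducible baseline, and callers can clip
directional kurtosis post hoc if desired.

**Degenerate voxels.** Voxels with non-positive or non-finite signals,
fitted MD ≤ 1e-9 mm²/s (no diffusion signal — the division X/MD² would
blow up), or non-positive apparent diffusivity anywhere on the quadrature
set are flagged invalid and carry NaN in every metric map; they are
excluded from ROI statistics, never silently zero-filled. The FA of an
all-zero diffusion tensor and the KFA of a zero kurtosis tensor are
defined as 0.

**Acquisition.** The emulated protocol is one b = 0 measurement plus 30
directions at each of b = 100, 1000, 2000 s/mm² (91 measurements, three
nonzero shells). Directions come from a deterministic Fibonacci-lattice
hemisphere, so no gradient table ships with the package. Gradient tables
are validated on construction: unit directions (±1e-6), ≥ 2 distinct
nonzero shells, ≥ 15 distinct nonzero-b directions.

## Scalar metrics

* d_mean = (λ₁+λ₂+λ₃)/3; FA = √(3/2)·√Σ(λᵢ−λ̄)²/√Σλᵢ² from the sorted
  eigenvalues of D.
* Axis conventions: `principal_eigenvector` (default; d_axial = λ₁,
  d_radial = (λ₂+λ₃)/2, kurtosis axis = e₁) or `anteroposterior` (axial
  along the fixed y axis, radial averaged over the perpendicular great
  circle). The anteroposterior convention exists because axial/radial can
  also be defined against an anatomical axis rather than the local fiber
  direction; d_mean, FA, k_mean and KFA are convention-independent.
* k_mean is the equal-weight quadrature average of K_app over a
  250-direction Fibonacci sphere lattice; k_radial averages K_app over 64
  equally spaced directions on the great circle perpendicular to the axis.
  K_app is a smooth rational function on the sphere, and 250 near-uniform
  directions give ≤ ~0.2% error against dense Monte-Carlo averages for
  physiologically valid tensors (checked explicitly in the tests). The
  closed-form elliptic-integral expression for the exact spherical mean is
  intentionally not used: the quadrature is simpler, verifiable against a
  brute-force oracle, and accurate well below the across-subject
  variability of the metric.
* **Eigenframe evaluation.** All kurtosis quadrature is evaluated in the
  eigenframe of D (the direction set is expressed in tensor-aligned
  coordinates). This makes every metric exactly equivariant under a joint
  rotation of (D, W) — the quadrature error depends on tensor shape, not
  pose — and makes the voxelwise (vectorised) and single-voxel code paths
  agree to machine precision.
* KFA = ‖W − W̄ I⁽⁴⁾‖_F/‖W‖_F with W̄ = (1/5)(W₁₁₁₁+W₂₂₂₂+W₃₃₃₃+2W₁₁₂₂+
  2W₁₁₃₃+2W₂₂₃₃); W̄ I⁽⁴⁾ is the orthogonal projection of W onto the
  isotropic rank-4 tensor (⟨I⁽⁴⁾, I⁽⁴⁾⟩ = 5), hence KFA ∈ [0, 1] exactly.

## Map pipeline

Smoothing is applied to the raw DWI volumes before fitting (the documented
behaviour of the established kurtosis-map tools): a per-axis Gaussian with
σ = FWHM/(2√(2 ln 2)) converted from mm to voxels (default FWHM 3 mm),
then a 3×3×3 median filter per measurement volume. The kernel size of the
median filter and the raw-vs-map smoothing order are not documented for
the original analysis; both defaults are exposed as options. Smoothing
mixes signal across region boundaries, so the phantom-fidelity checks run
with smoothing disabled.

Probability maps are thresholded strictly (p > 0.95 by default; the
inclusive/exclusive choice at the boundary is undocumented in the
workflows this emulates, and strict is the conservative reading). ROI
statistics use the sample SD (n−1); SEM = SD/√n. Across-subject
aggregation is the unweighted mean of per-subject ROI means (voxel counts
differ between subjects), with CV = SD/|mean|·100.

## Histology heterogeneity (HOG)

ROI images are converted to grayscale (BT.709 luminance weights; silver
stain is dark-on-light, so no inversion) and tiled into non-overlapping
squares of round(100 µm / pixel size) pixels; partial border tiles are
discarded. Per tile:

1. first-order gradients by central differences (borders zero);
2. per 20×20-px cell, an 8-bin magnitude-weighted histogram of unsigned
   gradient orientation over [0°, 180°), hard bin assignment;
3. contrast normalisation over 2×2-cell blocks with the L1 norm
   (stabilising ε = 1e-12 by default) and sliding one-cell stride;
   non-overlapping blocks are available via configuration.

The implementation is bit-compatible with `skimage.feature.hog` (the
standard reference implementation of this descriptor) when configured
with the same ε, and the test suite asserts that agreement; it is
reimplemented in-package because the configurable block stride and ε are
not exposed there. The tile statistic is the sample SD and the excess
(Fisher) kurtosis — population moment ratio m₄/m₂² − 3 — of the feature
vector; Pearson (non-excess) kurtosis is available via a flag. ROI-level
values are unweighted means over non-degenerate tiles (pooled-vector mode
is exposed as an alternative). Tiles with (near-)zero gradient variance
are flagged degenerate and excluded.

Because each block is L1-normalised, multiplying tile intensities by a
constant rescales every cell histogram identically and cancels in the
ratio: per-tile kurtosis is invariant to brightness scaling up to the ε
term (≪ 1% over 0.5–2×, verified).

## Synthetic data

**Phantom tensors.** Regions are axially symmetric pairs: D has
eigenvalues (λ∥, λ⊥, λ⊥) about a chosen axis; W is transversely isotropic
with W₃₃₃₃ = K∥λ∥²/MD², in-plane W₁₁₁₁ = W₂₂₂₂ = 3W₁₁₂₂ = K⊥λ⊥²/MD²
(making K_app exactly K∥ on the axis and K⊥ in every perpendicular
direction; a closure check verifies both to 1e-9), and cross terms
W₁₁₃₃ = W₂₂₃₃ = (w_ax + w_perp)/6 so that an isotropic specification
yields exactly the isotropic tensor w·I⁽⁴⁾. When a region is specified by
its spherical-mean kurtosis instead of the (K∥, K⊥) pair, W is scaled to
match the quadrature mean exactly (K_app is linear in W).

The reference four-class phantom uses regional values from the
literature on the healthy brain: WM d_mean 0.60×10⁻³ mm²/s / k_mean 1.17
(λ∥ = 1.10, λ⊥ = 0.35×10⁻³, FA ≈ 0.62), GM 0.80×10⁻³ / 0.82 (FA ≈ 0.21),
SCN 0.46×10⁻³ / 1.17 (WM-like kurtosis in predominantly grey tissue),
CSF 2.07×10⁻³ / 0.74 (near-isotropic). The eigenvalue splits are chosen
so FA falls in each class's realistic range; the grid is 40×40×16 voxels
(2 mm slices) tiled by axis-aligned boxes.

**Noise.** Rician by default — S' = √((S+ε₁)² + ε₂²), ε ~ N(0, (S0/SNR)²)
— the magnitude-MRI model; Gaussian and noiseless modes exist. All
randomness flows through one seeded generator recorded in the output
metadata, so outputs are byte-reproducible.

**Fiber textures.** The histology generator emulates a silver-stained
section as a dense field of faint overlapping fibers: n = 3000 fibers per
800×800 px (0.5 µm/px) image, ~1.5 µm wide and ~75 µm long, each darkening
the background additively, then an optical-PSF-like Gaussian blur (0.6 µm)
and additive intensity noise. Orientations follow a von Mises
distribution on the half-circle (sampled on the doubled-angle circle);
κ = 0 is uniform. The dense additive design is deliberate: real stained
white matter is packed with overlapping axons, and it is the presence of
*many orientations within a single 10 µm cell* that flattens the
orientation histogram for incoherent tissue. Sparse isolated strokes do
not behave this way — with few fibers per cell, each cell is locally
coherent whatever the global κ, and spatial clumping then dominates the
feature-vector statistics. The default mean orientation (100°) sits at an
orientation-bin centre so that a coherent texture occupies one bin rather
than straddling the 0°/180° bin boundary.

What the generator does *not* emulate: stain variability, cell bodies and
neuropil background, vessels, section artefacts, or anisotropic PSFs.
Passing tests therefore show that the analysis chain responds correctly
to orientation coherence in a controlled texture family, not that it is
robust to all real-histology nuisance factors.

## Statistics

Pearson's r with two-sided p from the t statistic (n−2 dof), as
implemented in SciPy; pairs with < 3 complete rows or zero variance are
skipped and logged. Multiple-testing correction is Benjamini–Hochberg
step-up, applied across the full family of metric pairs tested in one
invocation (the family definition is logged); the implementation is
cross-checked against an independent brute-force step-up and against
statsmodels in the tests. Group-comparison omnibus testing (ANOVA +
post-hoc) is out of scope; the per-group summary tables needed to run it
externally are emitted.

## End-to-end pipeline and problem sizes

`run_end_to_end` chains phantom → (optional smoothing) → maps → masks/ROI
statistics → per-ROI fiber textures → HOG heterogeneity → correlation,
writing NIfTI/TIFF/CSV outputs and a provenance manifest (config hash,
seed, version) from which every output is reproducible. The default
configuration uses a 36×36×8 grid of nine regions (four WM, three SCN,
one GM, one CSF, values patterned on per-ROI literature ranges) and one
800-px histology image per WM/SCN region whose κ increases with the
region's diffusivity — planting the positive diffusivity-vs-histological-
kurtosis association the correlation stage should detect.

Default problem sizes (40×40×16 phantom fits, 20-seed × 4-κ histology
sweeps, 1e6-direction Monte-Carlo spherical averages, 150-replicate null
families) were chosen so the full verification runs in a few minutes on a
single CPU while keeping Monte-Carlo standard errors an order of
magnitude below the tolerances being checked.

## Known limitations

* No Rician noise-floor (bias) correction: at very low SNR or very high b
  the magnitude noise floor biases kurtosis estimates; the SNR-40 checks
  characterise the operating point, not the low-SNR regime.
* No registration, segmentation, distortion correction or tractography —
  co-registered inputs are assumed, as in the workflow this reimplements.
* The unconstrained fit can produce negative directional kurtosis in
  noisy voxels; such voxels are retained (flagged only when degenerate),
  matching the baseline estimator's behaviour.
* Histology analysis reads single-resolution 2-D images; whole-slide
  pyramids, stain deconvolution and cell counting are out of scope.
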