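# Methods

Model assumptions, parameter choices and numerical details for the
`hepamri` pipeline.  Units throughout: diffusivities in mm²/s, b values
in s/mm², PF as a fraction inside fitters and maps but as percent in
cohort tables, R2\* in s⁻¹, echo times in ms at interfaces (converted to
seconds internally).

## Forward models and fitters

### IVIM (intravoxel incoherent motion)

Bi-exponential magnitude signal

S(b) = S0·[PF·exp(−b·Dfast) + (1−PF)·exp(−b·Dslow)]

sampled at eleven b values (0, 20, 40, 60, 80, 100, 150, 200, 400, 600,
800 s/mm²).  Assumptions: two well-mixed compartments, no exchange,
mono-exponential decay per compartment, Dfast ≫ Dslow.

Fitting is a two-stage scheme:

1. **Segmented prefit.** A log-linear fit over b ≥ 200 (where the fast
   compartment has decayed) yields Dslow and an intercept whose ratio to
   the measured b=0 signal gives PF; the low-b residual then initializes
   Dfast.
2. **Bounded nonlinear least squares** on all four parameters
   (S0, PF, Dslow, Dfast) with an analytic Jacobian.  Bounds:
   Dslow ∈ [10⁻⁵, 5·10⁻³], Dfast ∈ [5·10⁻³, 0.5], PF ∈ [0, 0.7], S0 in
   [0.1, 10] on the b=0-normalized signal.  An identifiability guard
   requires Dfast ≥ 5·Dslow; when the optimizer fails to improve on the
   segmented solution, the segmented values are used and flagged
   (`used_fallback`).

Two map engines produce identical minima (tested): a per-voxel scipy
trust-region path (`engine="voxelwise"`) and a vectorized
bound-projected Levenberg–Marquardt over all voxels at once
(`engine="batch"`, default, ~20× faster; per-voxel damping and
accept/reject, parameters clipped to the bounds after each step).
A 50³-lattice grid search over (PF, Dslow, Dfast) serves as a test
oracle: the optimizer's residual may never exceed the best lattice
residual.

### DTI (diffusion tensor)

Single-shell tensor model ln(S/S0) = −b·gᵀDg with one b=0 volume and
twelve gradient directions at b = 500 s/mm².  The packaged direction set
was optimized by electrostatic repulsion (design-matrix rank 6,
condition number 1.62).  The fit is ordinary least squares on the
log-ratios against the six-column design matrix (off-diagonal columns
doubled); S0 is taken from the measured b=0 volume.  Metrics: MD =
trace/3; FA = √(3/2)·√Σ(λᵢ−MD)²/√Σλᵢ², clipped to [0, 1].  Negative
eigenvalues (noise) are clamped to zero for metric computation and
flagged.  Assumptions: Gaussian diffusion (no kurtosis), single
compartment, noise-free log-linearization is exact.

### BOLD relaxometry (R2\*)

Mono-exponential decay S(TE) = S0·exp(−TE·R2\*) over nine evenly spaced
echoes from 2.57 to 24.25 ms.  Default fit is log-linear (exact on
noise-free data); a nonlinear refinement (`method="nonlinear"`) is
available for low-SNR data where the log transform biases the slope.
Non-positive samples are dropped; fewer than three remaining echoes
invalidates the voxel.  The Rician noise floor flattens the apparent
decay, so R2\* is underestimated at low SNR — exercised in tests.

## Cohort generator

Each animal carries fourteen variables: six MR parameters (Dslow, Dfast,
PF, MD, FA, R2\*), six biochemical markers (ALT, AST, LDH, MDA, MPO,
SOD) and two ordinal histology scores (I, F on levels 0–2).

- **Marginals.** Continuous variables are Gaussian with group-specific
  location/scale equal to the observed group summaries.  Variables
  reported as median(IQR) (the skewed enzymes) use mean = median and
  SD = IQR width / 1.349 (the normal-distribution IQR-to-SD factor).
  Samples are clipped to positivity/physiology bounds.
- **Dependence.** A Gaussian copula targets a Spearman rank-correlation
  matrix via the latent-Pearson map r = 2·sin(π·ρ/6).  The default
  target embeds the observed MR-vs-reference correlation block; because
  that block alone (with unspecified blocks at zero) is not positive
  semidefinite in latent space, the latent matrix is projected to the
  nearest PSD correlation matrix (alternating projections) and mapped
  back.  This shrinks the strongest entries but preserves every sign —
  asserted in tests.  Generator scope: the copula reproduces marginals
  and pairwise rank dependence only, not higher-order structure.
- **Ordinal scores** are thresholded from the latent Gaussian at the
  cumulative pmf (control: degenerate at 0; model: (0.4, 0.4, 0.2) for
  I, (0.5, 0.4, 0.1) for F).
- **Identifiability floor.** Sampled Dfast is raised to at least
  5·Dslow, matching the fitter's separation guard; below that ratio the
  two compartments are not distinguishable on this b-value scheme and PF
  is unrecoverable even noise-free.

## Phantom rendering

A digital liver layout (default 40×40×5) is a tapered ellipse with
three small intrahepatic vessel discs.  Liver voxels draw parameters
with a 5% coefficient of variation around the animal truth (iid;
no spatial autocorrelation is modeled).  Vessel voxels get PF between
0.6 and 0.85 and ~3× the liver pseudodiffusion, so ROI placement must
avoid them.  Each animal gets a fixed random tensor orientation;
tensors are axisymmetric with the prescribed (MD, FA) via
δ = FA·√(3/(9−6·FA²)), λ = MD·(1+2δ, 1−δ, 1−δ).

**Noise.** Rician by default: √((S+σg₁)² + (σg₂)²) with σ = S0/SNR and
default SNR 50 at b=0 / first echo; background is then
Rayleigh-distributed with mean σ√(π/2).  Gaussian and noise-free modes
exist.  When fitting is restricted to the ROI union
(`fit_scope="roi"`), only those voxels are rendered and receive noise;
ROI statistics are identical to the full rendering (tested), and the
restriction makes repeated end-to-end runs cheap.

**Determinism.** All randomness descends from integer seeds through
`numpy.random.SeedSequence`; per-animal streams are keyed by
CRC-32 of the animal id (stable across processes, unlike `hash()`).

## ROI protocol and observers

Six circular ROIs of radius 2.0 px (13 pixels each, inside the
12 ± 2 protocol window), two per slice on the three central liver
slices, fully inside the liver, outside vessels, pairwise
non-overlapping; placement is seeded rejection sampling.  The animal
value of a map is the unweighted mean of the six per-ROI means (NaN
voxels excluded; an all-NaN ROI is dropped).  A second reader is
emulated by re-drawing each center within a jitter radius (default
2 px) under the same validity constraints; reader 1 provides the
analysis values, reader 2 only feeds the interobserver ICC.

## Statistics

- **Group comparison.** Pooled-variance two-sample t tests for
  mean ± SD variables (the MR parameters and MDA/MPO/SOD); Mann-Whitney
  U for the skewed enzymes (ALT/AST/LDH) and ordinal scores.  The
  Mann-Whitney statistic reported is the tie- and continuity-corrected
  normal-approximation Z (U in `estimate`); an exact enumeration mode
  matches brute force for small n (tested).
- **Correlations.** Spearman by default (Pearson available) between
  every MR and reference variable.
- **Agreement.** ICC(2,1) — two-way random effects, absolute agreement,
  single measure — computed from ANOVA mean squares with the
  McGraw–Wong F-based 95% CI; cross-checked against pingouin in the
  test extra.
- **Percent change.** Per model animal against the control-group mean,
  reported as mean ± SD in the expected direction (decrease for
  Dfast/PF, increase for R2\*).

## Numerical choices and limitations

- Problem sizes (grid 40×40×5, 10+10 animals, SNR 50) are package
  defaults chosen to run the full pipeline in under a second per seed
  on one CPU; all are configurable through `PipelineConfig`.
- The log-linear DTI and R2\* fits are exact on noise-free data but
  noise-biased at low SNR; the IVIM batch engine trades scipy's
  trust-region machinery for speed while provably matching its minima
  on the tested regimes.
- The generator does not model respiratory motion, partial volume,
  B0 inhomogeneity beyond mono-exponential R2\*, spatially correlated
  texture, or exchange between IVIM compartments.
- Image geometry (voxel sizes per protocol) is carried as NIfTI header
  metadata only; no computation depends on it.
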