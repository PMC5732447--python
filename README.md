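# hepamri

Multiparametric quantitative liver MRI pipeline for a simulated hepatic
warm ischemia–reperfusion injury (WIRI) study: IVIM diffusion, diffusion
tensor imaging and BOLD (R2\*) relaxometry, end to end from synthetic
cohort generation through voxelwise model fitting, ROI analysis and the
group-level statistical battery.

## Scientific problem

Warm ischemia–reperfusion injury — liver damage caused by temporarily
clamped blood inflow followed by reperfusion — alters tissue
microstructure and perfusion in ways that quantitative MRI can measure
noninvasively.  In a two-group animal experiment (injury model vs
sham-operated controls, ten animals per group), the injured liver shows:

- lower **Dslow** (true molecular diffusion), **Dfast** (capillary
  pseudodiffusion), **PF** (perfusion fraction) and **MD** (mean
  diffusivity), and
- higher **R2\*** (effective transverse relaxation rate, sensitive to
  deoxyhemoglobin),

with the MR parameters correlating against serum biochemistry
(ALT, AST, LDH, MDA, MPO, SOD) and ordinal histology scores
(inflammation I, fibrosis F).  Since the underlying animal data are not
publicly deposited, this package provides a fully synthetic, seeded
replica of the experiment: a cohort generator calibrated to the observed
group summaries and rank correlations, forward models for the three
acquisitions, the corresponding fitters, the six-ROI reading protocol
with a simulated second observer, and the statistical report.

## Models

| Modality | Forward model | Fitter |
|---|---|---|
| IVIM | S(b) = S0·[PF·e^(−b·Dfast) + (1−PF)·e^(−b·Dslow)], 11 b values 0–800 s/mm² | segmented log-linear prefit (b ≥ 200) + bounded nonlinear least squares; vectorized batch engine for maps |
| DTI | S(g) = S0·e^(−b·gᵀDg), b = 0 + 12 directions at b = 500 s/mm² | log-linear least squares on the rank-6 design matrix; MD = trace/3, FA from eigenvalue dispersion |
| BOLD | S(TE) = S0·e^(−TE·R2\*), 9 echoes 2.57–24.25 ms | log-linear (default) or nonlinear refinement; T2\* = 1000/R2\* |

The cohort generator couples all fourteen per-animal variables through a
Gaussian copula calibrated to Spearman rank-correlation targets; images
carry Rician magnitude noise (default SNR 50 at b=0 / first echo) over a
digital liver layout with intrahepatic vessels that ROI placement must
avoid.  Details and numerical choices are in
[docs/methods.md](docs/methods.md).

## Worked example

Run the full pipeline on a 10+10 cohort and inspect the report:

```python
from hepamri.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=7, n_control=10, n_model=10, snr=50.0)
result = run_pipeline(cfg)
cols = ["variable", "control_mean", "model_mean", "test", "statistic", "p_value"]
print(result.report["group_comparison"][cols].to_string(
    index=False, float_format=lambda v: f"{v:.4g}"))
```

Output:

```
variable  control_mean  model_mean         test  statistic   p_value
   Dslow      0.001296    0.001044            t       2.45   0.02476
   Dfast       0.03012     0.02354            t       2.84   0.01086
      PF         29.58       20.37            t      6.393 5.092e-06
      MD      0.001666    0.001468            t      3.034  0.007135
      FA        0.3661      0.3904            t     -1.598    0.1275
  R2star          96.8       120.7            t     -5.377 4.137e-05
     ALT         36.63       225.7 mann_whitney     -2.986  0.002827
     AST         62.83       378.5 mann_whitney     -1.475    0.1403
     LDH         485.7       812.1 mann_whitney     -1.134    0.2567
     MDA         1.998        3.59            t     -7.976 2.556e-07
     MPO          15.7       19.83            t     -2.718   0.01409
     SOD         170.6       118.8            t      7.849 3.209e-07
 I_score             0         0.8 mann_whitney     -2.767  0.005662
 F_score             0         0.8 mann_whitney     -2.442   0.01461
```

The expected WIRI pattern appears: diffusion and perfusion parameters
drop in the model group, R2\* rises, the skewed enzymes and ordinal
scores are routed to Mann-Whitney, the rest to the pooled t test.
Interobserver agreement between the two simulated readers:

```python
print(result.report["icc"].to_string(index=False, float_format=lambda v: f"{v:.3f}"))
```

```
variable   icc  ci_low  ci_high    model
   Dslow 0.999   0.998    1.000 ICC(2,1)
   Dfast 0.989   0.974    0.996 ICC(2,1)
      PF 0.998   0.996    0.999 ICC(2,1)
      MD 0.999   0.997    0.999 ICC(2,1)
      FA 0.995   0.989    0.998 ICC(2,1)
  R2star 0.997   0.994    0.999 ICC(2,1)
```

The same run is available from the command line, writing all artifacts
(cohort CSVs, report tables, manifest, config) to a directory:

```bash
hepamri run --seed 7 --out results/run7
```

Individual stages are exposed as `hepamri simulate` (writes NIfTI series
with FSL-style `.bval`/`.bvec` and echo-time sidecars), `hepamri
fit-ivim` / `fit-dti` / `fit-bold` (parametric maps from files),
`hepamri roi` (seeded six-ROI placement as JSON) and `hepamri analyze`
(statistics from an animal-level CSV).

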