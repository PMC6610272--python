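# Methods

This note records what `texsurv` computes, the conventions it fixes where
the field leaves choices open, what the synthetic data emulate, and the
known limitations of both.

## Volume of interest and tumour volume

Images and masks are NIfTI volumes sharing a voxel grid and spacing; no
world-coordinate resampling is performed (resampling policy is treated as
out of scope, as is registration between sequences). Masks may arrive as a
single 3-D file or as ordered per-slice 2-D files, which are stacked —
mirroring slice-wise free-hand ROI drawing assembled into a 3-D
segmentation. Any non-zero voxel counts as inside; disconnected components
are pooled. Tumour volume is `voxel count × dx·dy·dz / 1000` in cm³, by
default measured on the T2WI mask (the sequence volume is conventionally
read from); the choice is exposed because either mask is defensible.

## Texture features

Nine features per sequence. Conventions, fixed for testability where
commercial texture software leaves them unstated:

| choice | default | why |
|---|---|---|
| grey levels / histogram bins | 32 | common radiomics default; keeps the GLCM dense at typical VOI sizes |
| quantization | min–max equal width over within-VOI range | standard first-order radiomics definition; constant VOI → single level |
| GLCM offsets | 13 unique 3-D directions, distance 1, pooled before normalization | single matrix avoids per-direction aggregation choices; matches 3-D segmentation |
| GLCM symmetrization | on (add transpose) | conventional; makes `P` symmetric |
| log base | 2 (bits), `0·log 0 = 0` | must be fixed for exact tests |
| moments | population (n denominator) on **raw** intensities | entropy/uniformity live on the quantized histogram; variance/skewness/kurtosis on raw values |
| kurtosis | non-excess (Pearson; Gaussian → 3) | configurable to excess |

Zero-variance (constant) VOIs report skewness = kurtosis = 0 with a
degenerate flag. A single-voxel VOI has no neighbour pair; the GLCM is
degenerate and the constant-VOI limits (ASM 1, entropies 0, shade and
prominence 0) are reported.

Consequences asserted in tests: Σp = 1 and ΣP = 1; entropy = 0 ⇔
uniformity = 1 ⇔ constant VOI; all nine features invariant under
positive-slope affine intensity maps except variance (scales with slope²);
cluster shade negates and prominence is invariant under grey-level
inversion of a symmetric GLCM; and every feature agrees with an
independent exhaustive-enumeration implementation to 1e-9 relative
tolerance on small grids.

## Survival analysis

Records are per-patient rows (`pfs_months`, `event`, covariates). The Cox
partial likelihood is maximized via lifelines with the Efron tie
correction; no other tie method is implemented (requests for one raise).
Wald CIs are `exp(β ± 1.96·SE)`. Monotone likelihood / separation is
reported through a `converged=False` flag rather than silent output.
Screening fits one single-covariate model per candidate and retains
`p < α` (α = 0.05); the multivariate stage enters all retained covariates
together, with no stepwise removal. Continuous covariates stay on their
raw scales (the volume hazard ratio is per cm³). Stage variables enter
dichotomized: T 1–2 vs 3–4, N 0–1 vs 2–3, overall I–II vs III–IV. Because
uniformity lives on a 0–1 scale, its per-unit hazard ratio is extreme by
construction; the univariate report adds a per-0.01-unit column.

Kaplan–Meier estimation and the log-rank test come from lifelines and are
verified against hand-tabulated risk sets and a 500-simulation null
calibration.

## Evaluation

The 2-year outcome is progression by 24 months; records censored before 24
months are excluded from fixed-horizon analyses with a warning (the
synthetic cohorts guarantee ≥ 24-month follow-up for non-progressors, so
none are excluded there). Youden cutpoints scan every observed score value,
breaking ties toward the lower cutoff; the risk direction follows the
fitted coefficient sign (high risk = volume ≥ cutoff, high risk =
uniformity < cutoff). AUC is the Mann–Whitney concordance probability with
the Hanley–McNeil standard error; paired AUCs are compared with the
Hanley–McNeil z-test, approximating the score correlation by the average
of the within-class Pearson correlations. Sensitivity/specificity/PPV/NPV
carry Clopper–Pearson exact intervals. Harrell's C counts usable pairs with
half credit for risk ties; ΔC between two models on the same patients is
tested with a z whose variance is the leave-one-patient-out jackknife of
the difference (a paired patient bootstrap is available as an
alternative). Six models are compared, mirroring the emulated study:
uniformity, overall stage, tumour volume, and the Cox-linear-predictor
combinations uniformity+stage, uniformity+volume, uniformity+stage+volume.

## Synthetic data

Phantoms are ellipsoidal masks (semi-axis ratios 1.25 : 1 : 0.8, equal
enclosed volume to a sphere) voxelized on a regular grid, default spacing
0.75 × 0.75 × 4 mm (typical head-neck acquisition geometry). Intensities
are a bright rim at base 100 plus: a Gaussian noise field (SD =
`heterogeneity` × base, spatially smoothed), an optional darker concentric
core (necrosis), and optional multifocal patches (smoothed-field
exceedance sets with their own contrasts) — then rounded to integer grey
values, as MR magnitudes are stored. The rounding matters: min–max
quantization is invariant to pure intensity scaling, so it is the
occupied-integer-level count that lets the heterogeneity parameter drive
histogram uniformity (monotone: noise SD below one grey level →
uniformity → 1). The core and patches give the across-patient histogram
variation genuinely multi-factor structure rather than a single latent
noise scale. The two sequences share each patient's mask but draw all
intensity-structure parameters independently, so T2WI features carry no
prognostic signal and simply exercise the schema.

Cohorts draw per-patient phantom parameters (log-normal volumes, median
9 cm³; log-normal rim noise; uniform core fraction/contrast; Poisson
patch counts), extract features, then simulate PFS from an exponential
proportional-hazards model whose linear predictor acts **only** through
measured tumour volume (log HR = log 1.054 per cm³) and measured CE-T1WI
uniformity (log HR = −12 per unit — on the 0–1 uniformity scale this is a
strong protective effect whose printed per-unit hazard ratio rounds to 0,
the regime the emulated study reports). Covariates are centred at cohort
means so the baseline hazard (0.0055/month) is the typical-patient rate;
with administrative censoring uniform on 24–47 months it yields an event
fraction near 26/79 ≈ 0.33 and events concentrated in the first two
years. Non-progressors therefore have ≥ 24 months of follow-up exactly, by
construction. Stage (distribution 3.8 / 27.8 / 38.0 / 30.4% for I–IV), T
and N stage, sex (52/79 male) and age (46.6 ± 11.5, clipped to 15–73) are
drawn independently of the hazard. All randomness flows from explicit
seeds.

A separate screening-table generator reproduces the study-entry
arithmetic: 116 eligible patients with disjoint exclusion flags
(3 other malignancy, 1 distant metastasis at diagnosis, 17 no mass
formation, 16 incomplete follow-up) leaving 79 included.

What the synthetic data do **not** emulate: MRI physics (bias fields,
partial volume, coil profiles), anatomy, treatment effects, and the
absolute scale of the source study's uniformity values (its binning rule
is unknown; our 32-bin convention centres synthetic uniformity near
0.5–0.6 rather than near the published 0.856 cutpoint). Passing tests
therefore establish the pipeline's internal correctness and statistical
calibration on data with known structure — not agreement with any
patient-data estimate.

## Problem sizes used by tests and the acceptance script

Oracle comparisons run on grids up to 5×5×5; Cox recovery uses n = 1000
(two-group) and 100 null replicates of n = 200; log-rank calibration 500
simulations of n = 60; the end-to-end recovery experiment 50 replicates of
n = 300 patients at 2 × 2 × 4 mm phantom spacing (coarser than the default
spacing, chosen to keep per-replicate extraction light while preserving
several hundred voxels per tumour).

## Known limitations

- Only Efron tie handling; no time-varying covariates, PH diagnostics or
  competing risks.
- The Hanley–McNeil correlated-AUC correlation term is the usual
  within-class-correlation approximation of their table.
- The end-to-end recovery experiment shows an intrinsic limit of the
  screen-then-refit design rather than a software property: every CE-T1WI
  texture feature co-varies with uniformity (they are functionals of the
  same histogram/GLCM), so several correlated companions always pass the
  univariate screen, and each carries the nominal α-level chance of a
  false multivariate retention while collinearity inflates uniformity's
  conditional standard error. "Exactly the two true drivers significant"
  is therefore observed in only a minority-to-moderate fraction of
  replicates (≈ 24% at 50 replicates, n = 300) even though the drivers
  themselves, the Youden/KM stratification and the combined-model C-index
  ordering are recovered reliably. The per-replicate diagnostics are
  exposed by `texsurv.pipeline.recovery_replicates`.
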