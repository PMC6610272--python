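# texsurv

**3-D MRI tumour texture features with survival-model evaluation.**

`texsurv` re-implements, as a tested and reusable pipeline, a pretreatment-MRI
texture-prognosis analysis for nasopharyngeal carcinoma (NPC): first- and
second-order texture features and tumour volume are extracted from the tumour
volume of interest (VOI) on two MR sequences (T2-weighted and
contrast-enhanced T1-weighted, "T2WI" / "CE-T1WI"), screened against
progression-free survival (PFS) with Cox proportional-hazards models,
dichotomized at Youden-index cutpoints for Kaplan–Meier stratification, and
compared as prognostic models by fixed-horizon ROC analysis and Harrell's
C-index. A synthetic tumour-phantom and cohort generator stands in for
patient data, so the whole analysis runs end to end with no external inputs.

It is intended for methodologists and radiomics researchers who want a
transparent, scriptable version of this very common clinical-imaging study
design — e.g. to study its statistical behaviour on simulated cohorts.

## The statistics at the core

For a tumour VOI with within-mask intensities min–max quantized into
`N_g` grey levels with histogram probabilities `p_i`:

- entropy `= −Σ p_i log2 p_i` (bits), uniformity (energy) `= Σ p_i²`,
- variance / skewness / kurtosis: population central moments of the raw
  intensities (kurtosis non-excess),

and for the grey-level co-occurrence matrix `P(i, j)` (counts pooled over
the 13 unique 3-D direction vectors at distance 1, symmetrized,
normalized; marginal means `μ_x, μ_y`):

- GLCM entropy `= −Σ P log2 P`, angular second moment `= Σ P²`,
- cluster shade `= Σ (i + j − μ_x − μ_y)³ P`,
  cluster prominence `= Σ (i + j − μ_x − μ_y)⁴ P`.

Tumour volume is `voxel count × voxel volume / 1000` (cm³). Downstream:
univariate Cox screening at α = 0.05, a joint Cox refit of the retained
covariates (Efron tie handling), Youden cutpoints `argmax (sens + spec − 1)`
on the 2-year-progression outcome, Kaplan–Meier curves with the log-rank
test, AUC with Hanley–McNeil standard errors and the Hanley–McNeil
correlated-AUC z-test, and Harrell's C with a leave-one-patient-out
jackknife z-test for ΔC.

## Worked example

```python
from texsurv import CohortSpec, RunConfig, generate_cohort, run_full_analysis

features, clinical = generate_cohort(CohortSpec(n_patients=79, seed=7))
report = run_full_analysis(features, clinical, RunConfig(seed=7), "out/")
print(report.screen.retained)
print(report.cindex_table.round(3))
```

prints (seed 7; your numbers will match exactly):

```
('volume_cm3', 't2wi_kurtosis', 'cet1wi_entropy', 'cet1wi_uniformity',
 'cet1wi_variance', 'cet1wi_kurtosis', 'cet1wi_glcm_entropy',
 'cet1wi_angular_second_moment')
                         c_index   c_lo   c_hi
model
uniformity                 0.813  0.733  0.892
overall_stage              0.567  0.483  0.650
volume                     0.593  0.475  0.711
uniformity+stage           0.818  0.745  0.892
uniformity+volume          0.820  0.728  0.911
uniformity+stage+volume    0.822  0.735  0.909
```

The screen retains the two simulated hazard drivers (CE-T1WI uniformity and
tumour volume — the generator's defaults make higher uniformity and smaller
volume protective) together with their correlated texture companions; the
C-index table shows the uniformity-plus-clinical combinations outperforming
volume or stage alone, the pattern the pipeline is built to quantify.
`out/` then contains `features.csv`, `univariate.csv`, `multivariate.csv`,
`roc_table.csv`, `cindex_table.csv`, `comparisons.csv`, per-predictor
Kaplan–Meier tables/plots and `run.json`.

The same flow is available from the shell:

```bash
texsurv simulate --n 79 --seed 7 --out cohort/
texsurv run-all  --n 79 --seed 7 --out report/
texsurv extract  --image img.nii.gz --mask mask.nii.gz --sequence ce-t1wi
```

## Layout

- `src/texsurv/voi.py` — NIfTI image/mask pairs, VOI assembly, volume
- `src/texsurv/texture.py` — quantization, histogram + GLCM features
- `src/texsurv/survival.py` — Cox screening, Kaplan–Meier, log-rank
- `src/texsurv/evaluation.py` — Youden cutpoints, ROC/AUC, C-index
- `src/texsurv/synthetic.py` — tumour phantoms, cohort simulation, screening filter
- `src/texsurv/pipeline.py` — orchestration and report bundle
- `src/texsurv/cli.py` — `texsurv` command-line interface
- `docs/methods.md` — model, assumptions, parameter choices, limitations
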