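# collasig

Collagen-signature quantification from second-harmonic generation (SHG)
images of the gastric serosa, and competing-risk modelling of peritoneal
metastasis after radical gastrectomy.

Gastric cancer that invades the serosa sheds cells into the peritoneum,
and collagen reorganization in the serosal tumour microenvironment is
associated with that risk. This package implements the full analysis
chain a study of that question needs:

1. **Collagen quantification** — 146 features per SHG region of interest:
   12 morphological (GMM segmentation → fiber-network tracing →
   length/width/straightness/cross-links → Fourier orientation index),
   6 intensity-histogram features, 80 grey-level co-occurrence (GLCM)
   features (contrast/correlation/energy/homogeneity × displacements
   1–5 px × directions 0°/45°/90°/135°) and 48 Gabor features (mean and
   variance of response magnitude, 4 scales × 6 orientations).
2. **Collagen signature** — LASSO over the standardized features with
   5-fold cross-validation and the 1-SE rule on the 3-year event status;
   the signature is the sparse linear score Σβⱼ(vⱼ−μⱼ)/σⱼ, dichotomized
   by a Gray-statistic-maximizing cutoff search.
3. **Competing-risk model** — peritoneal metastasis (event 1) with
   deaths/other recurrences as competing events (event 2): Aalen–Johansen
   cumulative incidence F₁(t), a Gray-type k-sample test, Fine–Gray
   subdistribution-hazard regression (IPCW risk sets, robust SEs,
   SHR = e^β), a univariate p < 0.05 screen, and a nomogram mapping
   covariates → points → 3-year CIF via F₁(t|x) = 1−exp(−Λ₁₀(t)eˣᵝ).
4. **Evaluation** — averaged IPCW C-index, time-dependent ROC at 3 years
   with DeLong comparison, calibration against Aalen–Johansen bins,
   decision-curve net benefit NB = TP/n − FP/n·P_t/(1−P_t), and
   classification at the Youden-optimal cutoff.

Patient images from such studies are not public, so the package includes
synthetic generators with exact ground truth — fibrous SHG-like images
(controllable count, width, length, von Mises alignment) and cohorts
drawn from a Fine–Gray model with known coefficients — and every stage is
tested by parameter recovery against them. See `docs/methods.md` for the
model details and design choices.

## Worked example

The numbered scripts under `analysis/` run a complete simulated study
(40 patients × 5 ROIs, latent collagen severity with subdistribution
HR 2.5 per SD):

```bash
python analysis/01_simulate_study.py    # images + cohort + ground truth
python analysis/02_extract_features.py  # 146-feature vectors per ROI/patient
python analysis/03_build_signature.py   # LASSO signature + cutoff
python analysis/04_fit_nomogram.py      # screen + Fine-Gray + nomogram
python analysis/05_evaluate_model.py    # discrimination/calibration/utility
```

Output of one run (seed 2024):

```
LASSO selected 3 of 146 features at lambda=0.1547:
  glcm_contrast_d4_a0: -0.0439
  gabor_w32_o120_mean: +0.2654
  gabor_w32_o150_mean: +0.1633
univariate screen: signature p=6.0e-05 -> selected; clinical covariates dropped
multivariate Fine-Gray: signature SHR 10.36 (95% CI 3.31-32.47), p=6e-05
high vs low signature (cutoff -0.121): Gray-type chi2=10.32, p=0.0013
averaged C-index: 0.751 (95% CI 0.624-0.858)
3-year AUROC: 0.809 (DeLong CI 0.641-0.984)
classification at Youden cutoff 0.333: sens=0.938, spec=0.636, acc=0.815
```

The texture features stand in for the latent severity (which drives fiber
density, width and alignment in the generator), so the signature carries
the outcome signal; the inflated SHR relative to the simulated 2.5 per SD
reflects the signature's different scale and the small demonstration
cohort. The same chain is available as a library
(`collasig.pipeline.run_pipeline`) and a CLI
(`collasig simulate|extract|fit|evaluate|run`).

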