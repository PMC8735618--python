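# seropls

OPLS-DA classification of serum ¹H-NMR metabolomics integrated with
clinical chemistry, validated the hard way: matched-class repeated external
cross-validation against a permutation null, with ROC/Youden diagnostic
thresholding on the model's score axis.

## The problem

Can a binary clinical contrast — the motivating case is recent (< 12 months)
depressive symptoms in a NAFLD (non-alcoholic fatty liver disease) cohort —
be read out of fasting serum? The inputs are a cohort table (age, sex,
lipids, liver enzymes, HbA1c, ferritin, eGFR, BMI, liver stiffness,
medication flags) and one-dimensional ¹H-NMR serum spectra. Lipoprotein
methyl/methylene resonances (0.8–1.4 ppm), the inflammation marker GlycA
(~2.04 ppm) and glutamine (~2.45 ppm) are the candidate discriminators.

Because class imbalance, confounding covariates and small-n overfitting all
inflate naive accuracy estimates, the evidence machinery matters as much as
the model. The pipeline is:

1. **Preprocess** — total-area (or probabilistic-quotient) normalization of
   each spectrum outside the residual-water window; integration of named
   ppm bins; column-wise join with clinical chemistry; unit-variance (or
   Pareto) scaling.
2. **Model** — OPLS-DA: NIPALS PLS1 with one predictive component after
   removing `k` orthogonal components. For centered X and y ∈ {−1, +1}ⁿ the
   predictive weight is **w** ∝ Xᵀy; each orthogonal component is extracted
   from the loading **p** by removing its projection on **w** and deflating
   X by t_o p_oᵀ. Reported per model: R²X, R²Y, Q² (venetian-blind internal
   CV) and VIP_j = √(p·w_j²/‖w‖²) with mean squared VIP ≡ 1.
3. **Validate** — per repetition: subsample the majority class to the
   minority size (so chance = 50%), split into 10 stratified folds, fit on
   9, score the held-out fold with scaling statistics estimated on the
   training folds only; 100 repetitions. The identical procedure on
   label-permuted data builds the null; the two per-repetition accuracy
   distributions are compared with a two-sided two-sample
   Kolmogorov–Smirnov test.
4. **Diagnose** — an all-data model's score axis goes through ROC analysis
   (AUC with DeLong 95% CI) and Youden-index thresholding
   (J = sensitivity + specificity − 1); univariate backing via Welch's
   t-test with Bonferroni correction, one-way ANOVA with Tukey HSD,
   Pearson's χ², and ROUT outlier removal (Q = 0.1%).

A synthetic-cohort generator (`seropls.synthetic`) emulates the study
structure — 81 recent / 30 lifetime / 107 never-depressed subjects, group
effects injected in Cohen's-d units simultaneously on clinical variables
and on the matching simulated resonances, a shared latent lipid factor
coupling serum triglycerides to the CH₂ peaks — so the entire pipeline is
testable without patient data.

## Worked example

```python
from seropls import PipelineConfig, SimulationConfig, ValidationConfig, run_pipeline

cfg = PipelineConfig(simulation=SimulationConfig(),   # 81/30/107 cohort
                     validation=ValidationConfig(),   # 10 folds x 100 reps
                     comparison="recent_vs_rest", seed=1)
report = run_pipeline(cfg)
v, m = report["validation"], report["all_data_model"]
print(v["mean_accuracy_pct"], v["accuracy_ci95_pct"])
print(report["ks_vs_null"])
print(m["auc"], m["auc_ci95"], m["threshold_accuracy_pct"])
```

With seed 1 this prints a mean cross-validated accuracy of **61.2%**
(95% CI 60.7–61.8) against a permutation null at 49.9%, KS D = 0.88,
p ≈ 2×10⁻⁴⁶ — the signal is modest but unambiguously real. The all-data
model reaches AUC **0.78** (0.72–0.84) and classifies 66.1% of subjects
correctly at its Youden threshold. Ensemble model metrics are
R²X 19.2±0.7%, R²Y 27.0±3.2%, Q² 5.6±5.4%, and the top ensemble VIP
features are age (2.12), glutamine (1.67), HDL cholesterol (1.50) and the
VLDL/triglyceride methyl bin (1.46) — exactly the variables the generator
perturbs, ranked above all pure-noise features.

The same run from a shell:

```sh
seropls run --out-dir results/run1 --seed 1
```

writes `report.json` plus CSV side tables (scores, ROC points, VIPs,
univariate statistics) and the serialized model; a rerun with the same seed
is byte-identical.

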