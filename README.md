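# bivshape

Statistical shape analysis of bi-ventricular cardiac geometry.

Arrhythmogenic right ventricular cardiomyopathy (ARVC) remodels the right
ventricle in characteristic regional ways — dilation, outflow-tract
elongation, septal tilting, shortening, inlet/outlet bulging — that global
numbers like volumes and ejection fraction summarise poorly. `bivshape` is a
research toolkit for going beyond volumes: it builds population PCA shape
models of three corresponded cardiac surfaces (LV endocardium, LV epicardium,
RV endocardium), measures global shape differences with a currents kernel
metric, classifies patients from scalar shape features with a leave-one-out
kNN, and correlates shape-mode loadings with clinical diagnostic indices
(2010 Task Force Criteria counts, arrhythmic events). It is aimed at
researchers prototyping population shape statistics for cardiac imaging.

## The model in brief

Subjects are rows `x_i ∈ R^{3V}` of concatenated, rigidly aligned (rotation +
translation only — size is signal) vertex coordinates. The shape model is the
PCA of the sample covariance, computed in the dual:

    x ≈ x̄ + Σ_k ℓ_k √λ_k φ_k ,

with orthonormal modes `φ_k`, variances `λ_k`, and loadings `ℓ_k` in SD
units. The number of retained modes is the smallest m capturing 80 % of the
population variance. Two scalar shape features feed a k-nearest-neighbour
(k = 3) leave-one-out classifier: the currents distance to the control mean,

    d(a,b)² = ⟨a−b, a−b⟩,   ⟨a,b⟩ = Σ_ij exp(−‖c_i−d_j‖²/σ_w²)(n_i·m_j),

(triangle barycenters `c`, area-weighted normals `n`, Gaussian width σ_w =
10 mm), and the summed loading score `Σ_{k≤5} f_k |ℓ_k − μ_k^ctrl|/s_k^ctrl`
(variance-fraction-weighted, control-normalised). Loadings are tested against
clinical indices with Spearman ρ, Kendall τ_b, Pearson r and a five-mode CCA,
at p < 0.05, uncorrected (an exploratory screen).

No patient imaging data is included. A synthetic cohort generator plants five
orthonormal deformation modes (44/15/10/7/5 % of total variance plus 19 %
thin residual noise) on a stylised bi-ventricle template and links clinical
indices stochastically to the planted loadings, so the full pipeline is
testable end-to-end with known ground truth. A 27-patient reference table of
diagnostic indices is bundled for the clinical-bookkeeping utilities. See
`docs/methods.md` for assumptions and numerical choices.

## Worked example

```bash
bivshape run-all --config examples/demo_config.yaml --out demo_out
```

simulates a 27-patient ARVC-like and a 21-subject control-like cohort
(seed 1), aligns them, fits the shape models and prints a report
(`demo_out/report.json`) like:

```
"n_modes_80pct": {"ARVC": 5, "control": 3, "pooled": 3},
"variance_fractions_arvc_first5": [0.586, 0.086, 0.069, 0.049, 0.019],
"currents_distance": {"loo_knn_accuracy": 0.646, "loo_knn_sensitivity": 0.704,
                      "loo_knn_specificity": 0.571, "roc_auc": 0.765, ...},
"summed_score":      {"loo_knn_accuracy": 0.563, "roc_auc": 0.732, ...},
"n_significant_associations": 26
```

Reading it: the ARVC-like model needs 5 modes to reach 80 % of the shape
variance, and its first mode captures 59 % on this single draw — individual
27-subject cohorts scatter widely around the planted 44 % (seed-averaged
fits recover it within ±3 points; see below). The currents distance to the
control mean classifies with 65 % LOO accuracy (AUC 0.77), the summed
regional score with AUC 0.73, and 26 of 192 uncorrected association tests
flag at p < 0.05 — the planted loading–index links plus the expected ~5 %
false positives. Classification strength here reflects the demo's group
effect sizes, which are free simulation parameters. Per-subject distances,
scores, predictions, ROC points and the full association table are written
as CSVs next to the report, with a manifest for bitwise reproducibility.

The clinical utilities work standalone:

```python
>>> from bivshape import load_reference_table, tfc_category, bsa_dubois
>>> table = load_reference_table()
>>> len(table), table.records["vt_vf"].sum()
(27, 12)
>>> tfc_category(1, 2)
'definite'
>>> round(bsa_dubois(70, 175), 3)
1.848
```

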