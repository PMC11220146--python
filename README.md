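# pathoscore

Whole-slide **pathomics scoring**: a reusable, tested pipeline that predicts a
binary molecular label (high vs. low expression of a marker such as MMP9)
from the texture of H&E-stained slide images, and carries the resulting
per-patient **pathomics score (PS)** through survival and gene-set
enrichment statistics.

The pipeline is aimed at computational-pathology researchers who want the
classical (non-deep-learning) pathomics workflow as composable,
well-specified Python: every stage is a library function or sklearn-style
estimator, and a synthetic-cohort generator with planted texture,
expression, and survival structure makes the whole chain testable without
any external download.

## The method

1. **Tiling.** Tissue is separated from the white background by Otsu
   thresholding of the grayscale slide. The slide is cut into a
   non-overlapping grid of square tiles — 1024 px at 40×, 512 px at 20×
   (upsampled to 1024 px) — tiles with more than 50 % white pixels are
   excluded, and 10 tiles are sampled uniformly per slide.
2. **Texture features.** Per tile: first-order statistics plus gray-level
   co-occurrence (GLCM) and run-length (GLRLM) matrix features on a
   32-level discretization, direction-averaged. Per patient: the mean over
   the 10 sampled tiles, then z-score standardization with training-cohort
   parameters.
3. **Feature selection.** mRMR keeps the top 20 features by the MID
   criterion — maximize I(f; y), penalize the mean mutual information with
   already-selected features — then linear-SVM RFE eliminates the
   smallest-|w| feature until 6 remain.
4. **Models.** A linear soft-margin SVM (C = 1) with Platt-scaled
   probabilities, and a backward-stepwise-AIC logistic regression. The PS
   of a patient is the predicted probability of the high-expression class.
5. **Validation.** ROC/AUC with DeLong variance and tests, ACC/SEN/SPE/
   PPV/NPV at a Youden-optimal threshold, stratified tenfold CV with all
   preprocessing refit per fold, Hosmer–Lemeshow calibration, Brier score,
   and decision-curve analysis.
6. **Survival.** Kaplan–Meier, log-rank, minimum-p-value dichotomization of
   a continuous marker (minprop 0.1), and Cox proportional hazards (Efron
   ties) with subgroup interaction terms.
7. **Enrichment.** Genes ranked by Spearman correlation with the PS;
   preranked GSEA (weighted KS statistic, 1000 gene-set permutations,
   significance at p < 0.05 and FDR < 0.25); Spearman correlations of
   curated gene lists; rank-sum comparison of externally supplied
   immune-cell fraction tables between PS groups.

## Worked example

```python
import numpy as np
from pathoscore import (CohortConfig, generate_cohort, kfold_cv,
                        logrank_test)
from pathoscore.texture import feature_matrix

cfg = CohortConfig()          # 78 patients, planted texture effect, HR 1.9
cohort = generate_cohort(cfg)
fm = feature_matrix(cohort.slides(), seed=1)       # 78 x 30 feature table
y = cohort.labels().loc[fm.index].to_numpy()       # high-marker class
scores, roc = kfold_cv(fm, y, k=10, seed=0)        # pooled out-of-fold PS
print(f"tenfold CV AUC: {roc.auc:.3f}")

clin = cohort.clinical_table().set_index("patient_id").loc[fm.index]
ps_group = (scores > scores.median()).astype(int).to_numpy()
chi2, dof, p = logrank_test(clin[["time_months", "event"]], ps_group)
print(f"log-rank p (high vs low PS): {p:.4f}")
```

Output:

```
tenfold CV AUC: 0.973
log-rank p (high vs low PS): 0.0307
```

The AUC says the texture features recover the planted class signal almost
perfectly under cross-validation; the log-rank p says patients with a high
pathomics score die significantly earlier, as expected when the marker
class carries a hazard ratio of 1.9.

A YAML-driven command-line interface runs the same stages end to end and
writes CSV/JSON artifacts plus a manifest:

```bash
pathoscore run-all --config run.yaml --out runs/demo
```

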