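# cerebrad

Regional radiomics of cerebellar MRI with a sparse-representation classifier,
for studying whether cerebellar texture can identify cognitive impairment
(mild cognitive impairment and Alzheimer's disease versus healthy controls).

The package is a complete, reproducible desk pipeline:

1. **Synthetic cohorts** — multimodal 3-D phantoms (T1, T2, FLAIR) with a
   voxel-aligned 26-region parcellation of an ellipsoidal "cerebellum";
   diagnostic groups differ in regional mean intensity and in texture
   (spatial correlation length), with controllable effect sizes. Real
   co-registered NIfTI volumes plus a label map are accepted through the same
   interfaces.
2. **Radiomics features** — a fixed 57-feature catalogue per region per
   modality: 18 intensity features and 39 texture features from the
   gray-level co-occurrence (GLCM), run-length (GLRLM), size-zone (GLSZM)
   and neighbourhood gray-tone difference (NGTDM) matrices, all computed in
   3-D after 32-level min–max quantization. One modality over 26 regions
   gives a 1,482-feature vector; three modalities give 4,446.
3. **Sparse-representation classification (SRC)** — the test vector *f* is
   sparse-coded against the normalized training matrix
   F = [f₁¹ … f_m¹, f₁² … f_n²] by orthogonal matching pursuit,

       β̂ = argmin_β ‖f − Fβ‖₂² + γ‖β‖₀ ,

   per-class residuals r_c(f) = ‖f − F δ_c(β̂)‖₂ are compared, and the class
   with the smallest residual wins. Feature screening sparse-codes the ±1
   class indicator against the transposed training matrix and ranks features
   by accumulated coefficient magnitude over resampled repetitions.
4. **Evaluation** — stratified 2:1 cross-validation/test partition, 10-fold
   cross-validation with all state (imputer, normalizer, screening,
   dictionary) re-fit inside every training partition, held-out and
   external-cohort evaluation, and reports of accuracy, sensitivity,
   specificity, PPV, NPV, ROC points and AUC with repeat intervals.

## Worked example

```python
import cerebrad as cb
from cerebrad.evaluation import make_split, run_cv
from cerebrad.pipeline import build_feature_matrix
from cerebrad.synthetic import iter_cohort, generate_label_map

spec = cb.CohortSpec(n_per_group=8, grid_shape=(48, 48, 24), seed=1)
label_map = generate_label_map(spec)
subjects = [s for _, _, s in iter_cohort(spec, label_map=label_map)]
fm = build_feature_matrix(subjects)          # 24 x 4446 feature matrix

plan = make_split(fm.labels, ratio=(2, 1), n_folds=5, seed=2)
report = run_cv(fm, plan, positive=["MCI", "AD"], negative=["HC"])
print(report.summary())
```

prints (for these seeds):

```
task: MCI+AD (positive) vs HC (negative)
confusion: TP=11, FN=1, TN=6, FP=0
    accuracy: 0.944
 sensitivity: 0.917
 specificity: 1.000
         ppv: 1.000
         npv: 0.857
         auc: 1.000
```

i.e. of the 18 cross-validation subjects, one impaired subject was missed and
no control was called impaired; the continuous relative-residual score ranks
every impaired subject above every control (AUC 1.0).

The same pipeline is available from the shell:

```sh
cerebrad simulate --n-per-group 8 --seed 1 --out-dir runs/demo
cerebrad extract  --out-dir runs/demo
cerebrad evaluate --out-dir runs/demo --mode cv --task ci_vs_hc
```

## Fitting the classifier directly

`SparseRepresentationClassifier(X, y).fit()` returns an `SRCResults` object
carrying the sparse dictionary, the normalizer, the screened feature set and
`predict` / `decide` / `summary()` methods; `decide` exposes the per-class
residuals and the continuous score used for ROC curves.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the pipeline from scratch — generates a scaled-down synthetic cohort,
extracts the full 57-feature catalogue per region and modality, and runs the
split/cross-validation protocol on the cognitive-impairment task — printing
the metric reports it computes and writing the results JSON.

See `docs/methods.md` for the model, the generator's assumptions, numerical
conventions and known limitations.
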