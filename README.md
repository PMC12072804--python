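# icterus

Non-invasive jaundice screening from photographs: estimate serum total
bilirubin (mg/dL) from the color of the sclera — or of a urine sample —
photographed beside a known-white reference, and tune the bilirubin
threshold at which the estimate flags jaundice.

The package is aimed at researchers prototyping camera-based bilirubin
screening. Because no public image/bilirubin dataset exists for this
protocol, a synthetic cohort generator with known ground truth drives the
pipeline, so every stage — and the whole experiment — is reproducible and
testable offline. User-supplied photographs with masks can be ingested
through the same interfaces.

## Method

1. **White balance** (von Kries): with reference-patch channel means
   `(L₁, M₁, S₁)` and target white `(L₂, M₂, S₂) = (255, 255, 255)`, each
   pixel is scaled by the diagonal `D = diag(L₂/L₁, M₂/M₁, S₂/S₁)`,
   cancelling the per-photo illuminant cast.
2. **Color encoding**: full-range BT.601 YCbCr; bilirubin-driven yellowing
   depresses the blue channel and hence Cb.
3. **Regression**: from the masked RoI, either a 1567-dimensional feature
   vector (3×512-bin histograms + 3×10 moment statistics + log N) feeding
   tree models (CART, random forest of 500 trees, XGBoost), or the raw pixel
   set feeding a permutation-invariant DeepSets network
   `f(S) = ρ(mean φ(x))` implemented in NumPy.
4. **Evaluation**: stratified 5-fold cross-validation; OLS of truth on
   prediction (slope B, SE, R², mean difference ± SD); a threshold sweep
   over 1.0–4.0 mg/dL (step 0.1) maximising the Mann–Whitney AUC; confusion
   matrix (accuracy, precision, recall, F1) at the best threshold; exact
   McNemar comparison of the headline models.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
from icterus import RunConfig, run_experiment

report = run_experiment(RunConfig(seed=11))
for name, block in report["models"].items():
    reg = block["sclera"]["regression"]
    sweep = block["sclera"]["threshold_sweep"]
    print(f"{name:14s} R2={reg['r_squared']:.3f}  slope={reg['slope_B']:.3f}  "
          f"best_t={sweep['best_threshold']:.1f}  AUC={sweep['best_auc']:.3f}")
```

prints (about two minutes on one CPU):

```
decision_tree  R2=0.612  slope=0.684  best_t=2.4  AUC=0.964
deepsets       R2=0.842  slope=1.018  best_t=2.8  AUC=0.998
random_forest  R2=0.749  slope=1.135  best_t=2.4  AUC=0.987
xgboost        R2=0.751  slope=1.068  best_t=3.1  AUC=0.984
```

Reading: each row summarises pooled out-of-fold predictions for one model on
the scleral pathway of the default synthetic cohort (57 liver-disease cases,
31 controls). `R2` and `slope` come from regressing true bilirubin on the
prediction — the DeepSets network is both the most accurate (R² = 0.84) and
nearly perfectly calibrated (slope ≈ 1.0). `best_t` is the bilirubin cutoff
(mg/dL) that maximises the screening AUC: the strong models settle in the
mildly-elevated 2–3 mg/dL band, just below the 3 mg/dL level at which
scleral icterus becomes clinically visible. The same report also contains
the urine-pathway results (uniformly weaker, R² ≤ 0.28 here) and the exact
McNemar comparison of DeepSets vs random forest (p = 0.25 and 0.5 at their
respective best thresholds — no significant accuracy difference at n = 88).

The same experiment is available from the shell:

```sh
icterus run --seed 11 --outdir out/           # report.json + predictions.csv
icterus simulate --n-cases 57 --n-controls 31 --seed 0 --outdir data/
icterus extract --indir data/ --pathway sclera --outdir feats/
```

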