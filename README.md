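# eegemo

Emotional-state classification from 4-channel resting EEG.

`eegemo` is a tested, fully reproducible implementation of a common
affective-neuroscience analysis: classifying which emotional condition —
baseline rest, low arousal, high arousal, or social anxiety — a person was in
from a short eyes-open EEG recording taken with a consumer headband (channels
TP9, AF7, AF8, TP10 at 256 Hz). Because no public dataset exists for this
protocol, the package includes a first-class synthetic-cohort generator whose
condition effects follow the resting-EEG literature (e.g. reduced alpha and
elevated beta/gamma power under high arousal, elevated theta/beta under
social anxiety), so every stage of the analysis can be validated against
known ground truth.

## The analysis

1. **Preprocessing** — zero-phase 0.5–70 Hz band-pass, segmentation into 2-s
   epochs, per-epoch baseline correction, and automated artifact rejection
   (peak-to-peak, absolute amplitude, gradient and flatline thresholds).
2. **Features** — 54 per recording:
   * **FP** (20): absolute band power per channel in δ (0.5–4 Hz),
     θ (4–8), α (8–12), β (12–30), γ (30–50), estimated by per-epoch
     rectangular-window periodogram and averaged over epochs (µV²);
   * **DASM** (10): differential asymmetry FP(TP10)−FP(TP9),
     FP(AF8)−FP(AF7) per band;
   * **RASM** (10): the corresponding power ratios;
   * **CC** (10): Pearson correlation of the paired electrodes' per-epoch
     band-power series;
   * **FD** (4): per-channel Katz fractal dimension
     D = log₁₀n / (log₁₀n + log₁₀(d/L)).
3. **Selection** — features standardized and regressed on an arousal-ordered
   numeric label with lasso and ridge penalties; the selected set is the
   intersection of the two top-20 |coefficient| rankings.
4. **Classification** — XGBoost (η = 0.3, γ = 0, depth 6), RBF-kernel SVC
   (γ = auto) and L2 logistic regression (Newton-CG), evaluated with
   participant-grouped 5-fold cross-validation over all 6 binary and 4
   multiclass condition contrasts. Metrics: precision = TP/(TP+FP),
   recall = TP/(TP+FN), F1, accuracy and AUROC from an explicit
   TPR/FPR threshold sweep (macro one-vs-rest for multiclass), plus top-5
   total-gain feature importances from XGBoost.

## Worked example

```python
import eegemo as E
from eegemo.synth import default_profiles, ArtifactSpec

cohort = E.make_cohort(default_profiles(), ArtifactSpec(),
                       n_participants=6, duration=60, seed=7)
epochs = [E.preprocess_recording(r) for r in cohort]
table = E.extract_table(epochs)                 # (24, 56): 54 features + ids
sel = E.select_features(table, k=20, seed=0)
report = E.run_full_benchmark(table, sel, seed=0, n_folds=3)
df = report.metrics_frame()
print(df[df.classifier == "xgboost"][["condition", "accuracy", "auroc"]].head(6))
```

prints (560 of 720 epochs survive rejection; 12 features are selected):

```
                     condition  accuracy  auroc
       baseline vs low_arousal      0.50   0.50
      baseline vs high_arousal      0.75   0.75
    baseline vs social_anxiety      1.00   1.00
   low_arousal vs high_arousal      0.75   0.75
 low_arousal vs social_anxiety      1.00   1.00
high_arousal vs social_anxiety      1.00   1.00
```

Contrasts involving social anxiety separate perfectly even in this small,
noisy 6-participant cohort (its theta/beta boost plus frontal asymmetry
offset is the largest planted effect); baseline vs low arousal — a single
moderate alpha increase against between-participant variability — sits near
chance, exactly the gradient one expects from the generator's effect sizes.

The same pipeline runs from the shell:

```bash
eegemo run-all --out runs/demo --seed 7 --n-participants 6
```

writing `features.csv`, `selection.csv`, `metrics.csv`, `importance.csv`,
`roc_points.csv`, `report.json` and a log, each stamped with the config hash.

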