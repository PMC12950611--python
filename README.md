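# flimcore

Analysis pipeline for label-free **fluorescence lifetime imaging (FLIm)** of
fresh prostate biopsy cores. A single-fiber probe scans each core under
pulsed 355-nm excitation while autofluorescence decays are recorded in four
spectral bands (collagen, NAD(P)H, FAD, porphyrins); the temporal decay
shape is a label-free contrast mechanism for tissue state — high-grade
cancer shortens the NAD(P)H-band lifetime as metabolism shifts toward
glycolysis. The package is written for researchers developing or evaluating
such optical-biopsy protocols: it provides the full chain from raw decay
waveforms to patient-aware classifier validation, plus a synthetic cohort
generator so every stage is testable without clinical data.

## What it does

1. **Simulate** (`flimcore.simulate`) — a multi-patient cohort of biopsy
   cores: class-specific multi-exponential decays per band, patient-level
   random effects, bidirectional repeat scans, pulse-level noise with
   4-pulse averaging, and fixation shrinkage between fresh-core and
   histology coordinates.
2. **Deconvolve** (`flimcore.deconvolve`) — constrained least-squares
   Laguerre-expansion deconvolution of every waveform. With basis `B` and
   coefficients `c`, it solves

   ```
   min_c ‖y − (irf ∗ B)c − b·1‖²   s.t.  Bc ≥ 0,  Δ(Bc) ≤ 0
   ```

   as an exact convex QP (dual nonnegative least squares), and emits per
   band the average lifetime (center of mass of the fitted decay), the
   spectral intensity, and 12 shape-only Laguerre coefficients — 56 stored
   parameters per point, 52 of them used for classification.
3. **Label** (`flimcore.labeling`) — maps histology annotations onto scan
   positions assuming uniform specimen deformation and excludes the 25
   points (~0.54 mm) straddling every label transition.
4. **QC** (`flimcore.qc`) — repeat-scan repeatability: 18-point smoothing,
   noise estimation from raw-minus-smoothed, and significance of pass
   differences against a `3σ/√18` threshold.
5. **Classify** (`flimcore.classify`) — RBF SVM (box constraint 0.1,
   inverse-frequency class costs) evaluated with leave-one-patient-out
   cross-validation, patient-weighted pooled ROC-AUC, one-vs-one ECOC for
   the three-class task, patient-level bootstrap CIs, comparison
   classifiers (LDA/QDA/logistic/tree), and a deliberately naive 10-fold
   CV that quantifies patient-leakage inflation.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from flimcore import (CohortConfig, InstrumentConfig, sample_cohort,
                      build_laguerre_basis, extract_features)
from flimcore.labeling import build_labeled_dataset
from flimcore.classify import prepare_dataset, run_three_class
import pandas as pd

inst = InstrumentConfig()                      # 460 Hz, 2.5 GS/s, 4 bands
cfg = CohortConfig(n_patients=12, cores_per_patient=(3, 5),
                   core_length_mm=(5.0, 9.0), rng_seed=1)
cohort = sample_cohort(cfg, inst)
basis = build_laguerre_basis(0.8, 12, inst.n_samples)
ops = {}
feats = pd.concat([extract_features(s, inst, basis, operators=ops)
                   for s in cohort.scans if s.pass_index == 0],
                  ignore_index=True)
labeled = build_labeled_dataset(
    feats, {t.core_id: t for t in cohort.tracks},
    {l.core_id: l.fresh_length_mm for l in cohort.layouts})
res = run_three_class(prepare_dataset(labeled), rng_seed=0)
for cls, m in res.per_class.items():
    print(cls, round(m.auc_weighted, 3))
```

prints (seed 1, this cohort):

```
benign 0.979
GP3 0.797
GP4+ 0.974
```

— the expected hierarchy: high-grade disease (GP4+) separates well, the
intermediate pattern GP3 overlaps both neighbors and scores lowest, and
benign tissue is recovered in between. On the same cohort the naive
point-level 10-fold AUC for GP4+-vs-rest is 0.986 against 0.973 for LOPO:
random folds leak patient structure and flatter the classifier.

## Command line

```
flimcore run --seed 1 --out results/run          # full pipeline + report.md
flimcore simulate / deconvolve / label / qc / classify   # individual stages
flimcore classify --features labeled.csv --task three_class \
    --model svm_rbf --validation lopo --bootstrap 100 --seed 1 --out result.json
```

The numbered scripts under `analysis/` run the same stages as a narrated
sequence (`01_simulate_cohort.py` … `06_calibration_studies.py`), writing
artifacts under `results/analysis/`.

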