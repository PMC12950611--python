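# Methods

`flimcore` implements an end-to-end analysis of fiber-probe fluorescence
lifetime imaging (FLIm) scans of fresh prostate biopsy cores: a synthetic
cohort generator, constrained Laguerre-expansion deconvolution of the raw
decay waveforms, registration of histology annotations onto the fresh-core
axis, a repeat-scan repeatability statistic, and malignancy classification
under leave-one-patient-out (LOPO) validation. This note records the models,
the defaults and their rationale, and the known limitations.

## Instrument model and protocol constants

The acquisition geometry is fixed by a few constants: 355-nm excitation at a
460 Hz repetition rate, a 2.5 GS/s digitizer (0.4 ns per sample), a scan
speed of 2.5 mm/s, block-averaging of 4 consecutive pulses, four detection
bands (390/±20, 470/±14, 542/±25, 629/±26.5 nm, matched to collagen,
NAD(P)H, FAD and porphyrin/lipofuscin emission), and a 400 µm lateral
resolution of the ball-lensed probe. Everything downstream derives from
these: the point spacing `2.5 mm/s × 4 / 460 Hz ≈ 21.74 µm` (quoted as
22 µm), the 25-point transition-exclusion zone (≈ 0.54 mm), the 18-point
smoothing window of the repeatability statistic (≈ 0.4 mm), the
spacing-to-resolution ratio (≈ 5%, the fraction of points that are
effectively independent), and the feature count 4 bands × (1 lifetime + 12
Laguerre coefficients) = 52. The record length defaults to 680 samples
(272 ns), long enough for nanosecond decays to vanish; the default
instrument response function (IRF) for simulation is a unit-sum Gaussian of
1.5 ns FWHM peaking 16 ns into the record, leaving a pre-pulse baseline
region. All of these are configuration fields, not hard-coded numbers.

## Laguerre deconvolution

A measured waveform is modeled as `y = irf * h + b·1 + ε` with the decay
`h = B c`, where `B` is the discrete orthonormal Laguerre basis (order 12)
built by the standard recursion, `c` the expansion coefficients and `b` a
free constant baseline. The coefficients solve the convex quadratic program

    min_c ‖y − (irf*B)c − b·1‖²   s.t.   Bc ≥ 0,  diff(Bc) ≤ 0,

i.e. the fitted decay must be nonnegative and nonincreasing. The QP is
solved exactly through its dual, a nonnegative least-squares problem whose
active set is at most the coefficient count; a Lawson–Hanson active-set
iteration specialized to this wide, low-rank geometry is JIT-compiled with
numba (~0.5 ms per fit), with scipy's reference NNLS as the independent
oracle in the tests and as a runtime fallback. When the unconstrained
least-squares solution already satisfies the constraints (to 1e-8 of the
decay peak) it is returned as-is.

Two numerical choices matter and were made deliberately:

* **Basis scale.** `alpha = 0.8` by default. The order-0 Laguerre function
  decays as `alpha^(n/2)`, an effective 3.6 ns time constant at 0.4 ns
  sampling; 12 orders then represent decays from ~1 ns to ~8 ns. A slower
  basis (`alpha = 0.9`) cannot represent a 1 ns decay at all — the
  constrained fit smears it over several nanoseconds — while `alpha = 0.8`
  recovers every lifetime in the 1–8 ns range within ~1% noise-free.
  `alpha` is a config field; the basis property tests pass for any value in
  [0.8, 0.95].
* **Baseline term.** The protocol subtracts the mean of the pre-pulse
  region (first 5% of the record) before fitting. The *noise* of that
  estimate leaves a small DC pedestal, and a monotone-nonnegative decay is
  an excellent model of a DC pedestal: without countermeasures the fit
  tracks it as a long shallow tail and the center-of-mass lifetime blows up
  (errors of +250% at 1% noise were observed). Jointly fitting a free
  constant column removes this failure mode at negligible cost.

From the fit, three per-band feature groups are stored per point (56 values
total): the **average lifetime**, defined as the center of mass of the
fitted decay on a bin-centered time axis `t(n) = (n + ½)·dt` (bin-centering
makes the center of mass of a sampled exponential equal its time constant to
O(dt²); the plain grid convention is available as an option); the
**spectral intensity** `Σh·dt` of the deconvolved decay (IRF-independent by
construction); and the 12 **intensity-normalized Laguerre coefficients**
`c / (Σh·dt)`, which encode pure decay shape. The classification feature
set excludes the four intensities, leaving 52 parameters. The lifetime sum
is restricted to the support where the fitted decay exceeds 5e-4 of its
peak: over a 272 ns record the empty tail otherwise contributes rectified
noise with enormous leverage on the center of mass. The threshold trades a
small deterministic truncation bias (< 2% for the slowest decays simulated)
against noise robustness, and is configurable.

Calibration (recomputed by `analysis/06_calibration_studies.py` and the
acceptance script): at 40 dB peak SNR the median absolute lifetime error
over τ ∈ {1, 2, 4, 6, 8} ns is ~2%.

## Synthetic cohort

No public FLIm biopsy dataset exists, so the generator produces a cohort
with the statistical structure the analysis depends on. Its defaults are
synthetic choices, not measured values:

* **Decay models.** Each tissue class (benign, Gleason pattern GP3, GP4,
  GP5) has a two-exponential decay per band. In the 470 nm (NAD(P)H) band
  the intensity-weighted mean lifetimes are ordered GP5 < GP4 < GP3 <
  benign (≈ 2.5 / 2.8 / 3.5 / 4.4 ns), emulating the shorter tumor
  lifetimes expected from the glycolytic shift (more free NADH); the other
  bands carry the same ordering with weaker contrast.
* **Heterogeneity.** A per-patient, per-band lifetime offset (SD 0.40 ns)
  models between-patient biological and instrumental variation — this is
  the random effect that makes naive point-level cross-validation
  optimistic. A per-position jitter (SD 0.35 ns, shared by both passes)
  models within-core tissue texture. Patient tissue composition is drawn
  from a Dirichlet around the prevalence weights (benign-dominated, with a
  self-balancing correction so cohort-level class fractions track the
  prevalence), and a fix-up guarantees every class appears in ≥ 2 patients
  so LOPO evaluation is defined for every class. These SDs were chosen so
  the default cohort lands in the performance regime reported for real
  tissue (GP4+ detection AUC ≈ 0.9+, GP3 intermediate and clearly harder,
  naive 10-fold visibly inflated); they were fixed before the acceptance
  assertions (which test orderings, not levels) were written.
* **Acquisition.** Each position's true decay is convolved with the IRF,
  peak-normalized with a lognormal intensity factor (σ = 0.15), repeated
  per pulse with additive zero-mean Gaussian noise (SD 1% of peak), and
  block-averaged by 4 — the same operation the instrument performs. The
  reverse pass shares the true decays with independent noise (the
  repeatability null); an optional drift hook adds a lifetime offset to
  pass 1 in a chosen fraction of cores for QC power studies. Fixation
  shrinkage multiplies all annotation boundaries by a uniform factor drawn
  from 0.85–1.15.
* **Sizes.** 20 patients, 4–8 cores each, core lengths 5–12 mm (the
  instrument supports up to 19 mm); at 21.74 µm spacing this yields roughly
  10⁵ two-pass point measurements and ~4×10⁵ deconvolutions per cohort,
  sized so the full default analysis runs in minutes on one CPU.

What the generator does *not* emulate: blood or saturation artifacts,
spatially correlated (smooth) within-core texture, non-uniform fixation
deformation, inter-band correlation of the random effects, and any real
tissue optics. Passing tests therefore demonstrate that the *pipeline* is
correct and the *protocol* behaves as designed, not that real prostate
tissue is classifiable at these AUC levels.

## Registration and labeling

Histology annotations live on the fixed-core axis; under the
uniform-deformation assumption position `x` maps to the fresh core as
`x · fresh_length / histology_length`. Points take the label of the
containing interval (half-open `[start, end)`; the distal core tip closes
the final interval); points outside every interval stay unlabeled and never
enter training or evaluation, but remain in the feature table. At every
label transition (including transitions into unlabeled gaps) 25 points are
excluded, straddling the boundary — 13 on the earlier side, 12 on the later
side — because 25 × 21.74 µm ≈ 0.54 mm matches the stated physical extent
of the exclusion zone, whereas 25 per side would double it. Exclusion is
applied per pass. On synthetic cohorts, where uniform shrinkage is exactly
the model, label accuracy against ground truth is 100%.

## Repeatability statistic

Per core and band, the two passes' lifetime traces are smoothed with an
18-point centered moving average (edge-truncated and renormalized). The
measurement noise SD `σ_raw` is the sample SD of (raw − smoothed) of the
forward pass; smoothed traces then carry `σ_raw/√18`. The scan-level
verdict compares the mean absolute difference between the smoothed passes
with `3·σ_raw/√18` (a ~99% confidence threshold). Per-point flags
additionally apply a √2 pair correction — the difference of two
independently noisy traces has twice the variance of one — without which a
3σ per-point threshold flags ~3.4% of null points rather than < 1%. Two
further caveats are documented rather than corrected: smoothing leaves
residual autocorrelation (the threshold treats smoothed samples as
independent), and `σ_raw` absorbs any true within-core variation faster
than the resolution, making the statistic conservative on structured
tissue. The Monte-Carlo null calibration therefore asserts an empirical
flag rate ≤ 2% rather than exactly 1%; measured: ~0.3% on trace-level
nulls, ~0–1% on full waveform-level cohorts, with a planted 10σ offset
flagging every point and a planted 1 ns drift flagging essentially all
points of affected cores.

## Classification and validation protocol

Tasks: PCa (GP3+GP4+GP5) vs benign; GP4+ (GP4+GP5) vs rest; and
three-class benign / GP3 / GP4+. GP5 is merged into GP4+ throughout.
Only forward-pass points are classified (the reverse pass is reserved for
QC). The default features are the four average lifetimes; the 52-parameter
set is selectable.

* **Model.** RBF-kernel SVM with box constraint C = 0.1. The kernel scale
  is the median pairwise distance on standardized training features (a
  deterministic heuristic, recorded in the result). Class imbalance is
  handled by misclassification costs inversely proportional to
  training-class frequency (mean-normalized); per-point weights are further
  scaled against a fixed reference total (1000), so the box constraint
  controls a fixed slack budget and results are invariant to duplicating
  the training data. Scores pass through a Platt-type logistic calibration
  fit on the training fold (AUC-neutral; affects operating points only).
  Three-class prediction uses a one-vs-one ECOC decomposition of three
  binary SVMs with probability-vote decoding. Comparison families (LDA,
  QDA, logistic regression, decision tree) use their native multiclass
  posteriors with cost-adjusted priors/weights.
* **Training decimation.** Adjacent points are near-duplicates (the probe's
  lateral resolution spans ~18 points), so training folds keep one point
  per resolution element (stride 18 along each core); scoring always uses
  every point. This respects the effective sample size of the data and
  makes the protocol (including its 100-replicate bootstrap) tractable.
* **Validation.** One LOPO fold per patient; out-of-fold class scores are
  pooled over all patients into a single ROC per class. Each point is
  weighted by the inverse of its patient's point count, so every patient
  contributes equally to the pooled ROC-AUC (the unweighted AUC is also
  reported). Ties integrate trapezoidally (midpoint convention).
  Operating points (sensitivity/specificity) are read at the maximum of
  Youden's J on the pooled weighted ROC; the rule is configurable.
* **Bootstrap.** Patient-level resampling with replacement, B = 100, CI =
  2.5th/97.5th percentiles; replicates that lose a class are dropped and
  counted. The default mode resamples patients' pooled out-of-fold scores
  (the classical cluster bootstrap of the pooled ROC); a full-retrain mode,
  in which every replicate reruns LOPO with duplicated patients appearing
  in other copies' training folds, is implemented and tested but costs
  ~100× a LOPO run.
* **Leakage comparison.** A deliberately naive point-level 10-fold CV
  (random folds ignoring patients) is evaluated with the same pooled
  weighted AUC. With patient random effects on, it is reliably optimistic
  relative to LOPO; with the patient effect off, the two agree closely —
  the expected exchangeability check.

## Problem sizes and runtime

Default end-to-end analysis (one CPU): cohort simulation ~1 min,
deconvolution of ~4×10⁵ waveforms ~3–4 min, labeling and QC seconds,
classification (two binary + three-class LOPO, bootstrap, naive 10-fold,
family comparison) ~2–3 min. The test suite reuses one default cohort via
a session fixture.

## Known limitations

* The constrained fit's lifetime retains a small positive noise sensitivity
  for sub-sample lifetimes (τ ≈ 1 ns: median error ~4–6% at 40 dB SNR).
* The support-restricted center of mass introduces a deterministic
  truncation bias (< 2% for the decays simulated) that trades against tail
  noise; applications with very long lifetimes should lower the threshold
  or extend the record.
* The per-point QC threshold's √2 pair correction assumes equal noise in
  both passes.
* The uniform-deformation registration is exact only because the simulator
  implements the same model; real fixation deformation is locally
  non-uniform, which is one reason transition exclusion exists.
* Bootstrap CIs in the default (score-resampling) mode ignore refit
  variability; the refit mode captures it at much higher cost.
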