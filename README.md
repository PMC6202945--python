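# motorbattery

Analysis pipeline for a 7-task smartphone motor-test battery (sustained
phonation, balance, gait, finger tapping, simple reaction time, rest
tremor, postural tremor) across three clinical groups (control, iRBD,
PD):

* **`synthgen`** — synthetic multi-task cohort generator with
  documented, tunable group effect sizes (including a zero-effect null
  configuration), so every downstream stage is testable without any
  clinical recordings. Effect magnitudes are test scaffolding, not
  estimates of any real cohort.
* **`sessionio`** — recording I/O, timestamp-based assembly of complete
  7-task sessions (30-min window, protocol order) and segmentation QC
  (energy-gated voice trimming, IMU transient trimming, flat-signal and
  minimum-duration gates).
* **`features_voice` / `features_motion` / `features_events`** — the
  998-feature battery: 330 phonation features (jitter, shimmer, HNR/NHR,
  PPE, RPDE, DFA, excitation ratios, glottal quotients, MFCC+deltas, f0
  statistics, vocal tremor modulation, spectral shape, wavelet bands),
  147 features per IMU task (time-domain, spectral, nonlinear, jerk and
  cross-axis categories; 588 total), 60 tapping and 20 reaction-time
  features. Tasks failing QC yield NaN blocks with the name set intact.
* **`selection`** — median imputation (train-split only), five ranking
  algorithms (LASSO path, mRMR, RELIEF, Gram-Schmidt forward selection,
  local-learning-based weights) and a majority-vote unified ranking
  (median rank, deterministic tie-breaking).
* **`classify`** — class-balanced random-forest validation of the three
  pairwise contrasts under 10-fold / leave-one-subject-out /
  leave-one-recording-out CV, with per-iteration sensitivity/specificity,
  randomized-prediction baselines, two-sample KS comparison,
  feature-count sweeps (2..30 step 2), sex-stratified subgroups and
  train/validation range-mismatch diagnostics. Everything (imputation,
  standardization, ranking, forest) is fit on the training split of each
  iteration only.
* **`report`** — task-salience percentages of the top-k features,
  accuracy-vs-feature-count curve tables and Markdown run reports.

## CLI

```bash
motorbattery synth    --out cohort/ --n-per-group 10 --effect-size 1.0 --seed 1
motorbattery extract  --in cohort/ --out features.csv
motorbattery rank     --features features.csv --contrast control_vs_pd --out ranks.csv
motorbattery validate --features features.csv --contrast irbd_vs_pd \
                      --scheme kfold10 --n-features 30 --seed 7 --out cv.csv
motorbattery report   --results cv.csv --rankings ranks.csv --out report/
```

## Notes

* The published headline accuracies of the motivating study were
  computed on an access-controlled clinical dataset; they are not
  reproducible here and are not claimed. The test suite instead verifies
  the structural and statistical contracts of the pipeline on synthetic
  cohorts (separable cohorts classify at high sensitivity/specificity;
  null cohorts sit at chance; randomized baselines are distinguished by
  KS only when real signal exists).
* The exact upstream feature tables and the segmentation algorithm were
  not published; the catalogs and QC gates here are documented
  reconstructions with fixed counts (330 + 60 + 20 + 4×147 = 998).
* Repeated recordings per subject let recording-level CV exploit
  subject identity (see the LOSO mismatch diagnostic); the synthetic
  generator exposes `subject_sd_frac` to control this confound.
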