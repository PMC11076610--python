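# hipfatigue

Hip-muscle fatigue from surface EMG, knee wobble from a wearable IMU, and
the link between them — as a reproducible analysis pipeline.

Clinicians lack a fast, low-cost way to quantify hip muscle motor fatigue.
Surface electromyography (sEMG) can measure it — during a sustained static
exercise the sEMG power spectrum compresses, so the mean frequency

    MNF = Σ f·P(f) / Σ P(f)

falls over time while signal amplitude holds or rises — but sEMG needs
equipment and expertise. A single knee-mounted accelerometer is cheap, and
growing "knee wobble" (the resultant acceleration ‖(ax, ay, az)‖) might
stand in for fatigue. This package implements the full analysis chain for
that question, for biomedical-signal and wearable-sensor researchers:

* **preprocessing** — 8th-order Butterworth bandpass (20–400 Hz) for sEMG,
  4th-order 10 Hz lowpass for the IMU (both zero-phase), 2 s trims, and
  segmentation of the remaining 86 s into ten equal intervals;
* **features** — per-interval MNF and mean rectified amplitude for three
  muscles (gluteus medius, gluteus maximus, rectus femoris) and four wobble
  measures of the resultant acceleration (max, AUC, sum of squares,
  zero-cross rate), normalized per subject;
* **statistics** — per-trial MNF/wobble regressions, first-vs-last paired
  t-tests, slope ANOVAs across muscles and activities, per-trial
  multivariate fits of summed MNF on the wobble measures, and stepwise
  selection (p-enter 0.05 / p-remove 0.10) of wobble measures with a time
  trend;
* **responder analysis** — fatigue responder = negative MNF slope with
  p < 0.05; wobble responder = any retained stepwise term with p < 0.05;
  wobble scored as a predictor of fatigue via PPV/NPV; plus a
  cost-sensitive 27-NN Chebyshev classifier (Kruskal–Wallis feature
  selection, false-positive:false-negative costs 4:1, stratified 5-fold CV)
  predicting any-muscle fatigue from acceleration features alone;
* **synthetic data** — a seeded generator of whole cohorts with programmed
  fatigue slopes and wobble growth, so every stage is testable against
  known ground truth (the study's raw recordings are not deposited).

## Worked example

The numbered drivers under `analysis/` run the study-sized experiment
(24 subjects × 5 activities = 120 trials, 90 s at 4370 Hz sEMG / 370 Hz
IMU) end to end, writing tables under `results/`:

```sh
python analysis/01_simulate_features.py   # cohort -> per-interval features
python analysis/02_regression_stats.py    # regressions, t-tests, ANOVAs
python analysis/03_responders_stepwise.py # responder labels, PPV/NPV, R² groups
python analysis/04_knn_classifier.py      # cost-sensitive KNN report
```

Output of a run with the default seed:

```
simulated 120 trials (24 subjects x 5 activities) in 15 s
feature table: 1200 rows (120 trials x 10 intervals)
MNF regressions: 360 muscle-trials; 73% negative slopes; mean relative slope -0.139 %/s
first-vs-last paired t-tests: 7/7 measures significant at 0.05: ['mnf_gmd',
'mnf_gmx', 'mnf_rf', 'acc_max', 'acc_auc', 'acc_ss', 'acc_zcr']
fatigue responders of 120 trials: GMD 54, GMX 62, RF 57; wobble responders 120
wobble -> any-fatigue: PPV 90% (108/120), NPV nan% (0/0)
multivariate R² by number of fatigued muscles:
  0 responders: n=12, mean R²=0.37
  1 responders: n=59, mean R²=0.96
  ...
KNN (27-NN, chebyshev, costs 1:4, 5-fold):
  PPV 92% (98/106), NPV 29% (4/14)
```

Reading this: about half the simulated muscle-trials were programmed as
fatigue responders, and the regression stage recovers them (54/62/57 flagged
per muscle). Every trial shows detectable wobble growth at the default
noise level, so wobble alone predicts fatigue with high PPV but provides no
negative evidence — the same high-PPV/low-NPV asymmetry the protocol is
designed to probe — while the KNN classifier trades a few positives for
some genuine negative predictive value. The multivariate R² climbing with
the number of fatigued muscles reflects the programmed coupling between
fatigue and wobble growth.

The same pipeline is available as one call (`hipfatigue.run(RunConfig(),
out_dir)`) or via the CLI (`hipfatigue simulate|run|classify --help`);
configs are plain YAML, and every random draw derives from the master seed,
so reruns are byte-identical.

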