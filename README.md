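# wristnms

Motor-unit-driven neuromusculoskeletal estimation of wrist kinematics.

Decomposed motor-neuron spike trains are converted into sliding-window spike
counts (DSC), mapped to muscle excitations by per-unit robust linear
regression with a median ensemble (ANN fallback for silent windows), and fed
through a simplified Hill-type wrist model in open-loop forward dynamics to
produce joint angles for three degrees of freedom (flexion/extension,
radial/ulnar deviation, pronation/supination). The package also implements
the classical interference-EMG baseline (TD features, PCA at 98 % variance,
per-DoF 3-neuron ANNs trained by Levenberg–Marquardt, best of 50 restarts),
tracking-based calibration with an antagonist-zero constraint, repetition-
level cross-validated evaluation, and a synthetic neuromuscular data
generator so that the whole pipeline runs without any recorded data.

## Modules

| Module | Contents |
| --- | --- |
| `wristnms.spike_features` | window grid, DSC matrix, activity masks |
| `wristnms.musculoskeletal` | 6-muscle Hill-type wrist model, activation dynamics, RK4 forward simulation |
| `wristnms.calibration` | kinematics scaler, antagonist mask, static optimization, tracking excitations |
| `wristnms.neural_mapping` | unit→muscle assignment, IRLS-bisquare unit regressors, median ensemble + ANN fallback |
| `wristnms.emg_baseline` | EMG preprocessing, TD features, PCA, LM-trained ANNs, post-hoc low-pass |
| `wristnms.synthetic_data` | task profiles, motoneuron pools, decomposition-like corruption, surrogate EMG, dataset generator |
| `wristnms.pipeline_eval` | single-DoF gating, end-to-end prediction, R²/RMSE, cross-validation, method comparison |

## CLI

```sh
wristnms simulate --seed 1 --out data/subject1        # 18 synthetic trials
wristnms calibrate --dataset data/subject1 --out cal1 # tracking excitations + report
wristnms evaluate --methods td,td_dsc,dsc_nms --folds 3 --repeats 10 \
    --seed 1 --out results.csv                        # cross-validated metrics
wristnms compare --results results.csv               # mean ± sd per method/DoF
```

`simulate`/`evaluate` accept `--config cfg.yaml` overriding any
`DatasetConfig` field (ranges of motion, pool sizes, corruption levels, EMG
channels, window grid, ...).

## Notes

- The wrist model is a self-contained stand-in (constant moment arms,
  rigid tendons, per-DoF lumped inertia with passive stiffness/damping
  holding the rest posture); all parameters are config-visible in
  `default_wrist_model` and serializable to YAML.
- The default window grid is 100 ms windows with a 90 ms step (10 ms
  overlap); a 10 ms-increment grid works everywhere downstream via
  `DatasetConfig.window_step`.
- Everything stochastic takes a seed and is exactly reproducible.
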