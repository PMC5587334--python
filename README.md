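# strfkit

Spike-triggered-average estimation of spectrotemporal receptive fields
(STRFs) with principled statistical correction, for auditory neurophysiology
at desk scale.

## The problem

The raw spike-triggered average (STA) of a dynamic-moving-ripple (DMR)
stimulus is an unbiased STRF estimator, but on a high-resolution grid (193
frequency bins x 200 1-ms lags) it is dominated by estimation noise: even a
pure-noise STA with 200 x 200 pixels is expected to keep ~400 "significant"
pixels after independent pixel thresholding at p < 0.01.  `strfkit`
implements and compares two families of corrections against circular-shift
null distributions:

1. **Pixel gain thresholding** (`p_gain`): spike times are circularly
   shifted by random offsets (spike counts and ISI structure preserved), an
   ensemble of 200 null STAs is built, and a normal distribution fitted to
   the pooled null pixel gains defines two-sided cutoffs; pixels inside the
   cutoffs are zeroed.
2. **Two-step cluster-mass thresholding** (`p_(gain,clst)`): survivors of a
   gain threshold are grouped into sign-pure connected components, and each
   cluster's mass (summed |gain|) is compared with a gamma distribution
   fitted to null cluster masses at the same gain level.

Both families come in joint and independent excitatory/inhibitory variants.
Corrected STRFs are validated by linear-nonlinear (LN) prediction: the STRF
is convolved with a repeated validation stimulus, half-wave rectified, and
correlated with the trial-averaged PSTH at bin sizes of 1-100 ms.
Thresholds on a 30-point log-spaced significance grid (p = 1 down to 1e-9)
are either fixed across units or selected per unit by cross-validation on
half of the validation data and scored on the held-out half.  Unit
screening (reliability index, trial similarity), stimulus-driven variance
slopes, and modulation-transfer analysis (ripple transfer functions, MTF
classification, best modulation frequencies) complete the workflow.

Because raw cortical recordings for this paradigm are not publicly
deposited, the package ships a first-class synthetic stack: a DMR envelope
generator with the standard modulation statistics and a
linear-nonlinear-Poisson (LNP) simulator with known ground-truth Gabor
filters, controllable baseline rate, drive modulation, and trial-to-trial
variability.

## Worked example

```python
import numpy as np
import strfkit
from strfkit.lnp import calibrate_gain
from strfkit.selection import analyze_unit

env_est = strfkit.generate_envelope(strfkit.DmrParams(duration=120.0, seed=1))
env_val = strfkit.generate_envelope(strfkit.DmrParams(duration=30.0, seed=2))
gt = strfkit.make_ground_truth_strf(strfkit.GaborSpec(), env_est.freq_axis,
                                    np.arange(200) * env_est.dt)
gain = calibrate_gain(gt, env_est, 8.0, modulation=0.7)
sd = strfkit.simulate_lnp(
    gt, env_est,
    strfkit.LnpParams(baseline_rate=8.0, gain=gain, trial_jitter_sd=0.2,
                      n_trials=20, seed=3),
    validation_env=env_val)

sta = strfkit.compute_sta(sd.estimation_spikes, env_est)
ens = strfkit.build_null_ensemble(sd.estimation_spikes, env_est, n_null=200, seed=4)
grids = strfkit.build_significance_grid(
    ens, gain_levels=np.append(strfkit.make_p_grid().retained_gain_levels, 0.05),
    stride_i=8)
result = analyze_unit(sta, grids, env_val, sd.validation_trials,
                      policies=("raw", "fixed_gain", "fixed_cluster",
                                "best_cluster"), n_iter=10, seed=5)
```

This prints (via `examples/04_validate_predictions.py`):

```
test-half prediction accuracy (10-ms bins, mean over 10 splits):
  raw             r = 0.190
  fixed_gain      r = 0.398
  fixed_cluster   r = 0.487
  best_cluster    r = 0.473
percent improvement of best cluster setting over raw: 149.3%
```

Read: the raw STA of this 1000-spike unit predicts the validation PSTH at
r = 0.19; zeroing pixels inside the p < 0.01 null gain band doubles
accuracy; the two-step correction (liberal p_gain < 0.05 gain threshold, then
a conservative p_clst < 1e-5 cluster-mass threshold) adds a further gain —
the same ordering the method is designed to establish.  Each script in
`examples/` demonstrates one capability (stimulus synthesis, LNP simulation,
correction, validation, modulation analysis) and prints what the numbers
mean.

A thin CLI mirrors the library (`strfkit simulate-dmr`, `simulate-neuron`,
`estimate`, `fit-nulls`, `correct`, `predict`, `screen`, `select`,
`modspec`, `run`, `report`); `strfkit run --config examples/pipeline_demo.yaml`
chains every stage on a 10-unit simulated population and writes per-unit
artifacts plus a population summary.

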