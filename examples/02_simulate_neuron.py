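"""Simulate a linear-nonlinear-Poisson cortical unit driven by a DMR.

A spectrotemporal Gabor filter plus half-wave rectification and Poisson
spiking, with a multiplicative lognormal rate factor per validation trial
to emulate intertrial variability.
"""

import numpy as np

import strfkit
from strfkit.lnp import calibrate_gain

env_est = strfkit.generate_envelope(strfkit.DmrParams(duration=120.0, seed=1))
env_val = strfkit.generate_envelope(strfkit.DmrParams(duration=30.0, seed=2))

spec = strfkit.GaborSpec(center_freq_oct=4.8, best_lag_s=0.03,
                         spectral_mod=0.6, temporal_mod=20.0,
                         exc_inh_ratio=1.8)
gt = strfkit.make_ground_truth_strf(spec, env_est.freq_axis,
                                    np.arange(200) * env_est.dt)
gain = calibrate_gain(gt, env_est, baseline_rate=8.0, modulation=0.7)

sd = strfkit.simulate_lnp(
    gt, env_est,
    strfkit.LnpParams(baseline_rate=8.0, gain=gain, trial_jitter_sd=0.2,
                      n_trials=20, seed=3),
    validation_env=env_val,
)

rate = len(sd.estimation_spikes) / sd.T_est
print(f"estimation segment: {len(sd.estimation_spikes)} spikes "
      f"({rate:.1f} spikes/s over {sd.T_est:g} s)")
counts = [len(t) for t in sd.validation_trials]
print(f"validation: {sd.n_trials} trials of {sd.T_val:g} s, "
      f"{np.mean(counts):.0f} +/- {np.std(counts):.0f} spikes per trial "
      "(spread reflects the 20% trial jitter)")
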