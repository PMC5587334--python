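"""Generate a dynamic-moving-ripple stimulus envelope.

The DMR drifts randomly through spectral modulations (0-4 cycles/octave)
and temporal modulations (-150..150 Hz), so that over minutes every ripple
configuration is sampled without bias.
"""

import numpy as np

import strfkit

params = strfkit.DmrParams(duration=60.0, seed=1)
env = strfkit.generate_envelope(params)

print(f"envelope: {env.n_freq} frequency bins x {env.n_time} time bins")
print(f"frequency span: {env.freq_axis[-1]:.2f} octaves above {env.f_low:g} Hz")
print(f"value range: [{env.values.min():.2f}, {env.values.max():.2f}] dB "
      f"(bounded by +/- mod_depth/2 = {params.mod_depth / 2:g} dB)")
print(f"per-frequency time-average magnitude: "
      f"{np.abs(env.values.mean(axis=1)).max():.3f} dB "
      "(long-term balance: approaches 0 with duration)")
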