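"""Shared fixtures: small DMR envelopes and a moderately driven LNP unit."""

import numpy as np
import pytest

import strfkit
from strfkit.lnp import calibrate_gain


def small_params(duration: float, seed: int, **over) -> strfkit.DmrParams:
    """A coarse frequency grid (about 49 bins) keeps unit tests fast."""
    kw = dict(duration=duration, freq_step=0.2, seed=seed)
    kw.update(over)
    return strfkit.DmrParams(**kw)


@pytest.fixture(scope="session")
def env20():
    """20-s estimation envelope on the coarse grid."""
    return strfkit.generate_envelope(small_params(20.0, seed=301))


@pytest.fixture(scope="session")
def env_val10():
    """10-s validation envelope on the coarse grid."""
    return strfkit.generate_envelope(small_params(10.0, seed=309))


@pytest.fixture(scope="session")
def env60():
    """60-s estimation envelope for the driven-unit fixture."""
    return strfkit.generate_envelope(small_params(60.0, seed=307))


@pytest.fixture(scope="session")
def gabor(env20):
    spec = strfkit.GaborSpec(
        center_freq_oct=4.5, best_lag_s=0.03, spectral_mod=0.5,
        temporal_mod=15.0, spectral_bw_oct=1.2, temporal_bw_s=0.015,
        exc_inh_ratio=1.8,
    )
    lag_axis = np.arange(200) * env20.dt
    return strfkit.make_ground_truth_strf(spec, env20.freq_axis, lag_axis)


@pytest.fixture(scope="session")
def driven_unit(env60, env_val10, gabor):
    """A driven LNP unit with trial jitter: spikes, STA and fitted grid."""
    gain = calibrate_gain(gabor, env60, 40.0, modulation=1.0)
    sd = strfkit.simulate_lnp(
        gabor, env60,
        strfkit.LnpParams(
            baseline_rate=40.0, gain=gain, trial_jitter_sd=0.2,
            n_trials=16, seed=303,
        ),
        validation_env=env_val10,
    )
    sta = strfkit.compute_sta(sd.estimation_spikes, env60)
    ens = strfkit.build_null_ensemble(sd.estimation_spikes, env60, n_null=60, seed=304)
    grids = strfkit.build_significance_grid(
        ens,
        gain_levels=np.append(strfkit.make_p_grid().retained_gain_levels, 0.05),
        sign_scopes=("both", "exc", "inh"),
        stride_i=2,
    )
    return {"spikes": sd, "sta": sta, "ens": ens, "grids": grids, "gt": gabor}


@pytest.fixture(scope="session")
def noise_unit(env20):
    """A stimulus-independent Poisson unit on the same stimulus."""
    rng = np.random.default_rng(305)
    spikes = np.sort(rng.uniform(0.0, env20.duration, rng.poisson(15 * env20.duration)))
    sta = strfkit.compute_sta(spikes, env20)
    ens = strfkit.build_null_ensemble(spikes, env20, n_null=60, seed=306)
    return {"spikes": spikes, "sta": sta, "ens": ens}
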