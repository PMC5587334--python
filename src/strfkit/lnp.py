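"""Ground-truth filters and linear-nonlinear-Poisson (LNP) spike simulation.

These simulated units stand in for DMR-driven auditory cortical neurons: a
spectrotemporal Gabor filter, half-wave rectifying output nonlinearity, and
inhomogeneous Poisson spiking, with optional multiplicative trial-to-trial
rate variability on the repeated validation segment.  Every downstream
operation (STA estimation, null thresholding, prediction scoring, screening)
is exercised against these units, whose generating filter is known exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._signal import linear_drive
from .dmr import StimulusEnvelope
from .exceptions import InvalidParameterError

__all__ = [
    "GaborSpec",
    "GroundTruthStrf",
    "LnpParams",
    "SpikeData",
    "make_ground_truth_strf",
    "simulate_lnp",
]


@dataclass(frozen=True)
class GaborSpec:
    """Parameters of a separable spectrotemporal Gabor subfield.

    The filter is the outer product of a spectral Gabor (Gaussian envelope
    times a cosine at ``spectral_mod`` cycles/octave, offset so that the
    excitatory peak exceeds the inhibitory trough by ``exc_inh_ratio``) and a
    temporal Gabor (Gaussian times cosine at ``temporal_mod`` Hz).  Cortical
    STRFs are predominantly excitation-dominated, hence the ratio default > 1.
    """

    center_freq_oct: float = 4.8
    best_lag_s: float = 0.030
    spectral_mod: float = 0.6  # cycles/octave
    temporal_mod: float = 20.0  # Hz
    spectral_bw_oct: float = 1.0  # Gaussian SD, octaves
    temporal_bw_s: float = 0.015  # Gaussian SD, seconds
    exc_inh_ratio: float = 1.8


@dataclass
class GroundTruthStrf:
    """Known generating filter, peak-normalized to max |value| = 1."""

    values: np.ndarray  # (n_freq, n_lag)
    freq_axis: np.ndarray
    lag_axis: np.ndarray
    spec: GaborSpec


@dataclass(frozen=True)
class LnpParams:
    """LNP forward-model parameters.

    ``rate(t) = trial_factor * max(0, baseline_rate + gain * (strf . env)(t))``
    with ``trial_factor`` drawn once per validation trial from a unit-mean
    lognormal with standard deviation ``trial_jitter_sd`` (exactly 1 when the
    SD is 0, and always 1 for the estimation segment).
    """

    baseline_rate: float = 10.0  # spikes/s
    gain: float = 1.0
    rectify: bool = True
    trial_jitter_sd: float = 0.0
    n_trials: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_rate < 0:
            raise InvalidParameterError("baseline_rate must be >= 0")
        if self.n_trials < 0:
            raise InvalidParameterError("n_trials must be >= 0")
        if self.trial_jitter_sd < 0:
            raise InvalidParameterError("trial_jitter_sd must be >= 0")


@dataclass
class SpikeData:
    """Spike times for one unit: estimation segment plus validation trials."""

    estimation_spikes: np.ndarray  # sorted, seconds in [0, T_est)
    validation_trials: list[np.ndarray]  # each sorted, seconds in [0, T_val)
    T_est: float
    T_val: float
    unit_id: str = "unit0"

    @property
    def n_trials(self) -> int:
        return len(self.validation_trials)


def make_ground_truth_strf(
    spec: GaborSpec, freq_axis: np.ndarray, lag_axis: np.ndarray
) -> GroundTruthStrf:
    """Construct a peak-normalized spectrotemporal Gabor on the given axes."""
    if spec.spectral_bw_oct <= 0 or spec.temporal_bw_s <= 0:
        raise InvalidParameterError("Gabor bandwidths must be positive")
    if spec.exc_inh_ratio <= 0:
        raise InvalidParameterError("exc_inh_ratio must be positive")
    x = np.asarray(freq_axis, dtype=np.float64) - spec.center_freq_oct
    tau = np.asarray(lag_axis, dtype=np.float64) - spec.best_lag_s
    # DC offset of the spectral cosine sets the excitatory:inhibitory ratio
    r = spec.exc_inh_ratio
    dc = (r - 1.0) / (r + 1.0)
    g_spec = np.exp(-0.5 * (x / spec.spectral_bw_oct) ** 2) * (
        np.cos(2.0 * np.pi * spec.spectral_mod * x) + dc
    )
    g_temp = np.exp(-0.5 * (tau / spec.temporal_bw_s) ** 2) * np.cos(
        2.0 * np.pi * spec.temporal_mod * tau
    )
    values = np.outer(g_spec, g_temp)
    peak = np.abs(values).max()
    if peak > 0:
        values = values / peak
    return GroundTruthStrf(
        values=values,
        freq_axis=np.asarray(freq_axis, dtype=np.float64),
        lag_axis=np.asarray(lag_axis, dtype=np.float64),
        spec=spec,
    )


def calibrate_gain(
    strf: GroundTruthStrf,
    env: StimulusEnvelope,
    baseline_rate: float,
    modulation: float = 0.7,
    t_max: float = 30.0,
) -> float:
    """Gain giving a target modulation index (drive SD / baseline rate).

    Filters with different bandwidths produce very different drive scales
    for the same stimulus; fixing the modulation index puts simulated units
    at a comparable signal-to-noise level.  The drive SD is estimated on the
    first ``t_max`` seconds of the envelope.
    """
    n = min(env.n_time, int(round(t_max / env.dt)))
    sd = linear_drive(strf.values, env.values[:, :n]).std()
    if sd == 0:
        raise InvalidParameterError("filter drive has zero variance")
    return modulation * baseline_rate / float(sd)


def _rate_series(
    strf_values: np.ndarray, env: StimulusEnvelope, params: LnpParams
) -> np.ndarray:
    drive = linear_drive(strf_values, env.values)
    rate = params.baseline_rate + params.gain * drive
    if params.rectify:
        np.maximum(rate, 0.0, out=rate)
    else:
        # contract: rates are never negative even without the nonlinearity
        np.maximum(rate, 0.0, out=rate)
    return rate


def _draw_spikes(
    rate: np.ndarray, dt: float, rng: np.random.Generator, factor: float = 1.0
) -> np.ndarray:
    """Time-binned thinning: at most one spike per bin, P = rate * dt."""
    p = np.clip(rate * factor * dt, 0.0, 1.0)
    hits = np.flatnonzero(rng.random(len(p)) < p)
    # uniform placement within the bin keeps times off bin edges
    return np.sort((hits + rng.random(len(hits))) * dt)


def simulate_lnp(
    strf: GroundTruthStrf,
    env: StimulusEnvelope,
    params: LnpParams,
    validation_env: StimulusEnvelope | None = None,
    unit_id: str = "unit0",
) -> SpikeData:
    """Simulate estimation and validation spike trains for one LNP unit.

    ``env`` drives the (unrepeated) estimation segment; ``validation_env``
    drives each of ``params.n_trials`` repeated validation trials.  The
    filter is applied causally with zero-padded history, so the first
    window-length of each segment reflects partial stimulation.
    """
    if strf.values.shape[0] != env.n_freq:
        raise InvalidParameterError(
            f"filter has {strf.values.shape[0]} frequency rows, "
            f"envelope has {env.n_freq}"
        )
    if params.n_trials >= 1 and validation_env is None:
        raise InvalidParameterError("validation_env required when n_trials >= 1")
    rng = np.random.default_rng(params.seed)
    est_rate = _rate_series(strf.values, env, params)
    est_spikes = _draw_spikes(est_rate, env.dt, rng)

    trials: list[np.ndarray] = []
    T_val = 0.0
    if params.n_trials >= 1:
        assert validation_env is not None
        if strf.values.shape[0] != validation_env.n_freq:
            raise InvalidParameterError("validation envelope frequency axis mismatch")
        val_rate = _rate_series(strf.values, validation_env, params)
        T_val = validation_env.duration
        if params.trial_jitter_sd > 0:
            s2 = np.log1p(params.trial_jitter_sd**2)
            factors = rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=params.n_trials)
        else:
            factors = np.ones(params.n_trials)
        for k in range(params.n_trials):
            trials.append(_draw_spikes(val_rate, validation_env.dt, rng, factors[k]))
    return SpikeData(
        estimation_spikes=est_spikes,
        validation_trials=trials,
        T_est=env.duration,
        T_val=T_val,
        unit_id=unit_id,
    )
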