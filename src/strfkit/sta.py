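"""Spike-triggered averaging and peristimulus time histograms.

The raw STRF estimator is the spike-triggered average (STA): the mean
mean-subtracted stimulus envelope preceding each spike, evaluated on a
frequency x lag grid (193 x 200 bins at the default 0.05-oct / 1-ms
resolution and 200-ms analysis window).  Because the DMR stimulus is
modulation-balanced, no stimulus-covariance correction is applied.

Values are per-spike means, so a merged train's STA is the spike-count
weighted mean of the parts.  The rate-relative-to-mean display scaling
(times spike count over duration) is available via ``rate_scaled``; every
downstream threshold is derived from null STAs with matched spike counts on
the same scale, so the analysis is invariant to this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dmr import StimulusEnvelope
from .exceptions import InvalidParameterError, NoSpikesError

__all__ = ["StrfEstimate", "Psth", "compute_sta", "compute_psth"]


@dataclass
class StrfEstimate:
    """A frequency-by-lag STRF estimate (raw STA or a corrected version).

    ``lag_axis`` ascends from 0 (the spike time) into the past.
    ``correction_tag`` records which correction pipeline produced the values
    ("raw", "gain", "gain_ei", "cluster", "cluster_ei"), with the applied
    significance settings in ``p_settings``.
    """

    values: np.ndarray  # (n_freq, n_lag)
    freq_axis: np.ndarray  # octaves
    lag_axis: np.ndarray  # seconds, ascending from 0
    n_spikes_used: int = 0
    correction_tag: str = "raw"
    p_settings: dict = field(default_factory=dict)

    @property
    def n_freq(self) -> int:
        return self.values.shape[0]

    @property
    def n_lag(self) -> int:
        return self.values.shape[1]

    @property
    def dt(self) -> float:
        return float(self.lag_axis[1] - self.lag_axis[0])

    @property
    def window(self) -> float:
        return self.n_lag * self.dt

    def rate_scaled(self, duration: float) -> np.ndarray:
        """Values scaled to spike rate relative to the mean (spikes/s units)."""
        return self.values * (self.n_spikes_used / duration)

    def copy_with(self, values: np.ndarray, tag: str, p_settings: dict) -> "StrfEstimate":
        return StrfEstimate(
            values=values,
            freq_axis=self.freq_axis,
            lag_axis=self.lag_axis,
            n_spikes_used=self.n_spikes_used,
            correction_tag=tag,
            p_settings=dict(p_settings),
        )


@dataclass
class Psth:
    """Trial-averaged peristimulus time histogram in spikes/s."""

    rate: np.ndarray
    bin_s: float
    n_trials: int


def _mean_subtracted(env: StimulusEnvelope) -> np.ndarray:
    """Envelope minus its per-frequency temporal mean (float32)."""
    z = env.values.astype(np.float32, copy=True)
    z -= z.mean(axis=1, keepdims=True, dtype=np.float64).astype(np.float32)
    return z


def _accumulate_windows(z: np.ndarray, bins: np.ndarray, n_lag: int) -> np.ndarray:
    """Sum of pre-spike envelope windows, columns ordered by ascending lag.

    ``bins`` are spike time-bin indices, each >= n_lag (early spikes already
    dropped), < n_time.  Returns sum_i z[:, b_i - m] for lags m = 0..n_lag-1.
    """
    acc = np.zeros((z.shape[0], n_lag), dtype=np.float64)
    uniq, counts = np.unique(bins, return_counts=True)
    for b, c in zip(uniq, counts):
        seg = z[:, b - n_lag + 1 : b + 1]
        if c == 1:
            acc += seg
        else:
            acc += c * seg
    return acc[:, ::-1]  # column j held lag n_lag-1-j; reverse to ascending lag


def compute_sta(
    spikes: np.ndarray,
    env: StimulusEnvelope,
    window: float = 0.200,
    z: np.ndarray | None = None,
) -> StrfEstimate:
    """Spike-triggered average of the mean-subtracted envelope.

    Spikes earlier than ``window`` are dropped (their pre-spike history would
    extend before the stimulus); spikes at or beyond the envelope duration
    are an error.  ``z`` may carry a precomputed mean-subtracted envelope to
    avoid recomputation across repeated calls on the same stimulus.
    """
    if window <= 0:
        raise InvalidParameterError("window must be positive")
    spikes = np.asarray(spikes, dtype=np.float64)
    if spikes.size and (spikes.min() < 0 or spikes.max() >= env.duration):
        raise InvalidParameterError(
            "spike time outside [0, T_est): "
            f"range [{spikes.min():g}, {spikes.max():g}], T_est={env.duration:g}"
        )
    n_lag = int(round(window / env.dt))
    kept = spikes[spikes >= window]
    if kept.size == 0:
        raise NoSpikesError("no spikes at or after the analysis window")
    if z is None:
        z = _mean_subtracted(env)
    bins = np.floor(kept / env.dt).astype(np.intp)
    np.minimum(bins, env.n_time - 1, out=bins)
    acc = _accumulate_windows(z, bins, n_lag)
    values = acc / kept.size
    lag_axis = np.arange(n_lag) * env.dt
    return StrfEstimate(
        values=values,
        freq_axis=env.freq_axis.copy(),
        lag_axis=lag_axis,
        n_spikes_used=int(kept.size),
        correction_tag="raw",
        p_settings={},
    )


def compute_psth(trials: list[np.ndarray], bin_s: float, T_val: float) -> Psth:
    """Trial-averaged PSTH with half-open bins [lo, hi).

    Spike times exactly at ``T_val`` are clamped into the last bin.
    """
    if len(trials) == 0:
        raise InvalidParameterError("PSTH requires at least one trial")
    if bin_s <= 0 or T_val <= 0:
        raise InvalidParameterError("bin_s and T_val must be positive")
    n_bins = int(np.floor(T_val / bin_s + 1e-9))
    counts = np.zeros(n_bins, dtype=np.float64)
    for t in trials:
        t = np.asarray(t, dtype=np.float64)
        idx = np.floor(t / bin_s).astype(np.intp)
        np.minimum(idx, n_bins - 1, out=idx)
        valid = idx >= 0
        counts += np.bincount(idx[valid], minlength=n_bins)
    rate = counts / (len(trials) * bin_s)
    return Psth(rate=rate, bin_s=bin_s, n_trials=len(trials))
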